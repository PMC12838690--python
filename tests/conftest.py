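"""Shared fixtures and the independent brute-force Sugeno evaluator."""

from __future__ import annotations

import math

import numpy as np
import pytest

from anfisctl.anfis import ANFISModel, InputSpec, MembershipFunction, Rule, gaussian_mf


def brute_force_sugeno(inputs, rules, x, n_outputs):
    """Independent weighted-average evaluator, written with plain loops.

    ``inputs`` is a list of (lo, hi, [(c, s1, s2), ...]); ``rules`` a list of
    (antecedent tuple, consequent nested list). Deliberately avoids the
    package's forward-pass code path.
    """
    degs = []
    for (lo, hi, mfs), xi in zip(inputs, x):
        xi = min(max(xi, lo), hi)
        row = []
        for c, s1, s2 in mfs:
            sig = s1 if xi <= c else s2
            row.append(math.exp(-0.5 * ((xi - c) / sig) ** 2))
        degs.append(row)
    w = []
    for ant, _ in rules:
        p = 1.0
        for i, k in enumerate(ant):
            p *= degs[i][k]
        w.append(p)
    total = sum(w)
    y = [0.0] * n_outputs
    xc = [min(max(xi, lo), hi) for (lo, hi, _), xi in zip(inputs, x)]
    for (ant, con), wi in zip(rules, w):
        for ch in range(n_outputs):
            f = con[ch][0]
            for j, xj in enumerate(xc):
                f += con[ch][j + 1] * xj
            y[ch] += (wi / total) * f
    return y


def random_model(rng, n_inputs=2, n_mfs=2, n_outputs=1, full_grid=True):
    """A random small Sugeno model plus its plain-data mirror for the oracle."""
    inputs = []
    mirror_inputs = []
    for i in range(n_inputs):
        centers = np.sort(rng.uniform(-1.0, 1.0, n_mfs))
        widths = rng.uniform(0.3, 1.0, n_mfs)
        mfs = [gaussian_mf(float(c), float(w)) for c, w in zip(centers, widths)]
        inputs.append(InputSpec(f"x{i}", -2.0, 2.0, mfs))
        mirror_inputs.append((-2.0, 2.0, [(float(c), float(w), float(w))
                                          for c, w in zip(centers, widths)]))
    if full_grid:
        from itertools import product
        ants = list(product(range(n_mfs), repeat=n_inputs))
    else:
        ants = [tuple(rng.integers(0, n_mfs, n_inputs)) for _ in range(n_mfs**n_inputs)]
    rules = []
    mirror_rules = []
    for ant in ants:
        con = rng.uniform(-2.0, 2.0, (n_outputs, n_inputs + 1))
        rules.append(Rule(tuple(int(a) for a in ant), con.copy()))
        mirror_rules.append((tuple(int(a) for a in ant), con.tolist()))
    model = ANFISModel(inputs, rules, n_outputs)
    return model, (mirror_inputs, mirror_rules)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_model():
    """1 input, 2 MFs, 2 rules, 1 output — hand-checkable."""
    spec = InputSpec("x", -5.0, 5.0, [gaussian_mf(-1.0, 1.0), gaussian_mf(1.0, 1.0)])
    rules = [
        Rule((0,), np.array([[1.0, 2.0]])),
        Rule((1,), np.array([[0.0, -1.0]])),
    ]
    return ANFISModel([spec], rules, n_outputs=1)
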