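"""Five-layer first-order Sugeno fuzzy inference.

The forward pass is: fuzzification -> product firing strengths ->
normalization -> affine rule consequents -> weighted-average aggregation.
Membership functions are either generalized bell curves or two-sided
(asymmetric) Gaussians sharing a single center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

# Degrees below this are flushed to zero so that products over many inputs
# cannot denormalize.
_UNDERFLOW = 1e-300


class InvalidParameterError(ValueError):
    """A membership-function or model parameter violates its constraint."""


class NoActiveRuleError(RuntimeError):
    """Every rule fired with strength zero; normalization is undefined."""


@dataclass
class MembershipFunction:
    """A single fuzzy set over one input.

    Parameters
    ----------
    kind : {"gbell", "asym_gaussian"}
        Functional form.
    c : float
        Center; ``degree(c) == 1`` for both kinds.
    a, b : float, optional
        Width and steepness of the generalized bell
        ``1 / (1 + |(x - c)/a|**(2b))``.
    s1, s2 : float, optional
        Left and right standard deviations of the two-sided Gaussian;
        the left branch applies for ``x <= c``.
    """

    kind: str
    c: float
    a: float | None = None
    b: float | None = None
    s1: float | None = None
    s2: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "gbell":
            if self.a is None or self.b is None:
                raise InvalidParameterError("gbell requires a and b")
            if self.a <= 0 or self.b <= 0:
                raise InvalidParameterError("gbell widths must be positive")
        elif self.kind == "asym_gaussian":
            if self.s1 is None or self.s2 is None:
                raise InvalidParameterError("asym_gaussian requires s1 and s2")
            if self.s1 <= 0 or self.s2 <= 0:
                raise InvalidParameterError("gaussian widths must be positive")
        else:
            raise InvalidParameterError(f"unknown membership kind {self.kind!r}")

    # -- evaluation ---------------------------------------------------------

    def degree(self, x):
        """Membership degree in [0, 1]; accepts scalars or arrays."""
        x = np.asarray(x, dtype=float)
        if self.kind == "gbell":
            z = np.abs((x - self.c) / self.a)
            out = 1.0 / (1.0 + z ** (2.0 * self.b))
        else:
            sigma = np.where(x <= self.c, self.s1, self.s2)
            out = np.exp(-0.5 * ((x - self.c) / sigma) ** 2)
        out = np.where(np.abs(out) < _UNDERFLOW, 0.0, out)
        return float(out) if out.ndim == 0 else out

    # -- premise-parameter packing ------------------------------------------

    @property
    def n_params(self) -> int:
        return 3

    def get_params(self) -> np.ndarray:
        if self.kind == "gbell":
            return np.array([self.a, self.b, self.c], dtype=float)
        return np.array([self.c, self.s1, self.s2], dtype=float)

    def set_params(self, p: Sequence[float], min_width: float = 1e-6) -> None:
        """Write back packed parameters, projecting widths to stay positive."""
        p = np.asarray(p, dtype=float)
        if self.kind == "gbell":
            self.a = max(float(p[0]), min_width)
            self.b = max(float(p[1]), min_width)
            self.c = float(p[2])
        else:
            self.c = float(p[0])
            self.s1 = max(float(p[1]), min_width)
            self.s2 = max(float(p[2]), min_width)

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "c": float(self.c)}
        if self.kind == "gbell":
            d.update(a=float(self.a), b=float(self.b))
        else:
            d.update(s1=float(self.s1), s2=float(self.s2))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MembershipFunction":
        return cls(**d)


def gaussian_mf(c: float, width: float) -> MembershipFunction:
    """Symmetric two-sided Gaussian (s1 == s2 == width)."""
    return MembershipFunction("asym_gaussian", c=c, s1=width, s2=width)


def membership_degree(mf: MembershipFunction, x: float) -> float:
    """Functional alias for :meth:`MembershipFunction.degree`."""
    return mf.degree(x)


@dataclass
class InputSpec:
    """One controller input: admissible range plus its fuzzy partition.

    ``wrap=True`` marks a periodic quantity (bearing error): out-of-range
    values are wrapped into ``(lo, hi]`` instead of clipped.
    """

    name: str
    lo: float
    hi: float
    mfs: list[MembershipFunction] = field(default_factory=list)
    wrap: bool = False

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise InvalidParameterError(f"{self.name}: empty range")
        for mf in self.mfs:
            if not (self.lo <= mf.c <= self.hi):
                raise InvalidParameterError(
                    f"{self.name}: MF center {mf.c} outside [{self.lo}, {self.hi}]"
                )

    def prepare(self, x: float) -> float:
        """Wrap (periodic inputs) or clip a raw value into range."""
        if self.wrap:
            period = self.hi - self.lo
            return self.lo + (x - self.lo) % period
        return min(max(x, self.lo), self.hi)

    def fuzzify(self, x: float) -> np.ndarray:
        return np.array([mf.degree(x) for mf in self.mfs], dtype=float)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "lo": float(self.lo),
            "hi": float(self.hi),
            "wrap": bool(self.wrap),
            "mfs": [mf.to_dict() for mf in self.mfs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InputSpec":
        return cls(
            name=d["name"],
            lo=d["lo"],
            hi=d["hi"],
            wrap=d.get("wrap", False),
            mfs=[MembershipFunction.from_dict(m) for m in d["mfs"]],
        )


@dataclass
class Rule:
    """One fuzzy rule: MF index per input, affine consequent per output.

    ``consequent`` has shape (n_outputs, n_inputs + 1); column 0 is the bias.
    """

    antecedent: tuple[int, ...]
    consequent: np.ndarray

    def to_dict(self) -> dict:
        return {
            "antecedent": [int(i) for i in self.antecedent],
            "consequent": [[float(v) for v in row] for row in np.atleast_2d(self.consequent)],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Rule":
        return cls(
            antecedent=tuple(d["antecedent"]),
            consequent=np.asarray(d["consequent"], dtype=float),
        )


@dataclass
class ForwardTrace:
    """Intermediate quantities of one forward pass."""

    memberships: list[np.ndarray]
    firing: np.ndarray
    normalized: np.ndarray
    rule_outputs: np.ndarray
    output: np.ndarray


def normalize_strengths(w: np.ndarray) -> np.ndarray:
    """w_i / sum(w); raises :class:`NoActiveRuleError` when sum(w) == 0."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise InvalidParameterError("firing strengths must be non-negative")
    total = w.sum()
    if total == 0.0:
        raise NoActiveRuleError("all rules fired with strength zero")
    return w / total


class ANFISModel:
    """A first-order Sugeno rule base over a fixed list of inputs."""

    def __init__(self, inputs: list[InputSpec], rules: list[Rule], n_outputs: int = 1):
        self.inputs = inputs
        self.rules = rules
        self.n_outputs = int(n_outputs)
        self._cache_dirty = True
        self._ant = None  # (n_rules, n_inputs) int
        self._con = None  # (n_rules, n_outputs, n_inputs + 1)
        self.validate()

    # -- bookkeeping --------------------------------------------------------

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    def validate(self) -> None:
        n_in = self.n_inputs
        for r in self.rules:
            if len(r.antecedent) != n_in:
                raise InvalidParameterError("antecedent length != number of inputs")
            for i, k in enumerate(r.antecedent):
                if not (0 <= k < len(self.inputs[i].mfs)):
                    raise InvalidParameterError(
                        f"rule antecedent index {k} invalid for input {self.inputs[i].name}"
                    )
            r.consequent = np.atleast_2d(np.asarray(r.consequent, dtype=float))
            if r.consequent.shape != (self.n_outputs, n_in + 1):
                raise InvalidParameterError(
                    f"consequent shape {r.consequent.shape} != "
                    f"({self.n_outputs}, {n_in + 1})"
                )

    def mark_dirty(self) -> None:
        """Invalidate cached rule tensors after mutating rules in place."""
        self._cache_dirty = True

    def _ensure_cache(self) -> None:
        if self._cache_dirty:
            self._ant = np.array([r.antecedent for r in self.rules], dtype=np.intp)
            self._con = np.stack([r.consequent for r in self.rules])
            self._cache_dirty = False

    # -- forward pass -------------------------------------------------------

    def prepare_inputs(self, x: Sequence[float]) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_inputs,):
            raise ValueError(f"expected {self.n_inputs} inputs, got shape {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite input")
        return np.array([spec.prepare(v) for spec, v in zip(self.inputs, x)])

    def memberships(self, x: Sequence[float]) -> list[np.ndarray]:
        xp = self.prepare_inputs(x)
        return [spec.fuzzify(v) for spec, v in zip(self.inputs, xp)]

    def firing_strengths(self, x: Sequence[float]) -> np.ndarray:
        memb = self.memberships(x)
        return self._firing_from_memberships(memb)

    def _firing_from_memberships(self, memb: list[np.ndarray]) -> np.ndarray:
        self._ensure_cache()
        w = np.ones(self.n_rules)
        for i, deg in enumerate(memb):
            w *= deg[self._ant[:, i]]
        w[w < _UNDERFLOW] = 0.0
        return w

    def forward(
        self, x: Sequence[float], double_weighting: bool = False
    ) -> tuple[np.ndarray, ForwardTrace]:
        """Evaluate the model at ``x``.

        ``double_weighting=True`` reproduces the literal printed composition
        in which the normalized strengths multiply the consequents twice; it
        exists for comparison only and breaks the convexity property.
        """
        xp = self.prepare_inputs(x)
        memb = [spec.fuzzify(v) for spec, v in zip(self.inputs, xp)]
        w = self._firing_from_memberships(memb)
        wbar = normalize_strengths(w)
        xa = np.concatenate(([1.0], xp))
        rule_out = self._con @ xa  # (n_rules, n_outputs)
        weight = wbar**2 if double_weighting else wbar
        y = weight @ rule_out
        return y, ForwardTrace(memb, w, wbar, rule_out, y)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Batch forward pass; returns (n_samples, n_outputs)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([self.forward(row)[0] for row in X])

    # -- premise-parameter packing (for the slow-timescale optimizer) -------

    def get_premise_params(self) -> np.ndarray:
        return np.concatenate([mf.get_params() for spec in self.inputs for mf in spec.mfs])

    def set_premise_params(self, alpha: Sequence[float]) -> None:
        alpha = np.asarray(alpha, dtype=float)
        i = 0
        for spec in self.inputs:
            for mf in spec.mfs:
                mf.set_params(alpha[i : i + mf.n_params])
                i += mf.n_params
        if i != alpha.size:
            raise ValueError("premise parameter vector has wrong length")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_outputs": self.n_outputs,
            "inputs": [s.to_dict() for s in self.inputs],
            "rules": [r.to_dict() for r in self.rules],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ANFISModel":
        return cls(
            inputs=[InputSpec.from_dict(s) for s in d["inputs"]],
            rules=[Rule.from_dict(r) for r in d["rules"]],
            n_outputs=d["n_outputs"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ANFISModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def copy(self) -> "ANFISModel":
        return ANFISModel.from_dict(self.to_dict())


def firing_strengths(model: ANFISModel, x: Sequence[float]) -> np.ndarray:
    """Functional alias for :meth:`ANFISModel.firing_strengths`."""
    return model.firing_strengths(x)


def forward(model: ANFISModel, x: Sequence[float], **kw):
    """Functional alias for :meth:`ANFISModel.forward`."""
    return model.forward(x, **kw)
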