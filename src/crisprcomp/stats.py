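"""Wilcoxon-Mann-Whitney comparison of spacer counts and its power.

``wmw_test`` computes the Mann-Whitney U statistic for the first sample
(number of pairs (x_i, y_j) with x_i > y_j, plus one half per tie).
Small pooled samples (n1 + n2 <= 12) get an exact two-sided p-value by
enumerating all labelings of the pooled data (mid-rank handling of ties
falls out of counting half-pairs per labeling); larger samples use the
normal approximation with tie correction and continuity correction, the
same recipe R's ``wilcox.test`` applies with ``correct = TRUE``.

``wmw_power`` estimates the test's power by Monte-Carlo simulation
under parametric sampling distributions (lognormal and exponential are
the families used for spacer-count comparisons), with the R parameter
conventions: ``lnorm(meanlog, sdlog)`` and ``exp(rate)``.
"""

from __future__ import annotations

import dataclasses
import itertools
import re

import numpy as np
import pandas as pd
from scipy import stats as sstats

EXACT_LIMIT = 12


@dataclasses.dataclass
class WmwResult:
    W: float
    p_value: float
    method: str  # {exact, normal_approx}


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    return float((x > y).sum() + 0.5 * (x == y).sum())


def wmw_test(x, y) -> WmwResult:
    """Two-sided Wilcoxon-Mann-Whitney test; see module docstring."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    if n1 + n2 <= EXACT_LIMIT:
        pooled = np.concatenate([x, y])
        center = n1 * n2 / 2.0
        dev = abs(u - center)
        hits = 0
        total = 0
        idx = range(n1 + n2)
        for combo in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(combo)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u_perm - center) >= dev - 1e-9:
                hits += 1
            total += 1
        return WmwResult(W=u, p_value=hits / total, method="exact")
    # normal approximation, tie-corrected, continuity-corrected
    n = n1 + n2
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return WmwResult(W=u, p_value=1.0, method="normal_approx")
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sstats.norm.sf(z))
    return WmwResult(W=u, p_value=p, method="normal_approx")


@dataclasses.dataclass
class DistributionSpec:
    """A named sampling distribution with R-style parameters."""

    family: str  # {lnorm, exp}
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family == "lnorm":
            if len(self.params) != 2 or self.params[1] <= 0:
                raise ValueError("lnorm needs (meanlog, sdlog) with sdlog > 0")
        elif self.family == "exp":
            if len(self.params) != 1 or self.params[0] <= 0:
                raise ValueError("exp needs (rate,) with rate > 0")
        else:
            raise ValueError(f"unknown distribution family {self.family!r}")

    @classmethod
    def parse(cls, text: str) -> "DistributionSpec":
        """Parse the printed-call form, e.g. ``lnorm(2.73, 0.62)``."""
        m = re.fullmatch(r"\s*(\w+)\s*\(([^)]*)\)\s*", text)
        if not m:
            raise ValueError(f"cannot parse distribution spec {text!r}")
        fam = {"lognormal": "lnorm", "exponential": "exp"}.get(m.group(1), m.group(1))
        params = tuple(float(p) for p in m.group(2).split(","))
        return cls(family=fam, params=params)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "lnorm":
            return rng.lognormal(self.params[0], self.params[1], size=n)
        return rng.exponential(1.0 / self.params[0], size=n)

    def mean(self) -> float:
        if self.family == "lnorm":
            return float(np.exp(self.params[0] + self.params[1] ** 2 / 2))
        return 1.0 / self.params[0]


@dataclasses.dataclass
class PowerSpec:
    n1: int
    n2: int
    dist1: DistributionSpec
    dist2: DistributionSpec
    alpha: float = 0.05
    reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be at least 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.reps < 1000:
            raise ValueError("reps must be at least 1000")


def wmw_power(spec: PowerSpec) -> float:
    """Monte-Carlo power of the two-sided test under ``spec``.

    Draws ``reps`` sample pairs, runs :func:`wmw_test` at level
    ``alpha`` and returns the rejection proportion.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    rejections = 0
    for _ in range(spec.reps):
        x = spec.dist1.sample(spec.n1, rng)
        y = spec.dist2.sample(spec.n2, rng)
        if wmw_test(x, y).p_value < spec.alpha:
            rejections += 1
    return rejections / spec.reps


#: conventional sufficiency threshold reported alongside power estimates
POWER_CONVENTION = 0.80


def array_size_summary(arrays) -> pd.DataFrame:
    """Spacer-count summaries per array class.

    Classes: canonical I-E, orphan I-E, I-E pooled, II-C.  Classes with
    no arrays are absent from the output (missing, not zero).
    """
    classes = {
        "I-E canonical": [a for a in arrays if a.system_type == "I-E" and a.context == "canonical"],
        "I-E orphan": [a for a in arrays if a.system_type == "I-E" and a.context == "orphan"],
        "I-E pooled": [a for a in arrays if a.system_type == "I-E"],
        "II-C": [a for a in arrays if a.system_type == "II-C"],
    }
    rows = []
    for name, group in classes.items():
        if not group:
            continue
        counts = [a.n_spacers for a in group]
        rows.append(
            {
                "class": name,
                "n_arrays": len(counts),
                "mean_spacers": float(np.mean(counts)),
                "max_spacers": int(np.max(counts)),
            }
        )
    return pd.DataFrame(rows, columns=["class", "n_arrays", "mean_spacers", "max_spacers"])


def compare_classes(arrays, class_a: tuple[str, str | None], class_b: tuple[str, str | None]) -> WmwResult:
    """WMW test between two array classes' spacer counts.

    A class is (system_type, context) with context None meaning pooled.
    """

    def pick(cls):
        st, ctx = cls
        return [
            a.n_spacers
            for a in arrays
            if a.system_type == st and (ctx is None or a.context == ctx)
        ]

    return wmw_test(pick(class_a), pick(class_b))
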