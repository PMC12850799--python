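"""Chance-corrected agreement between the algorithm and the human readers.

Paired gradings are cross-tabulated into a k x k contingency table (rows =
algorithm, columns = readers) and summarized by percent agreement, Cohen's
kappa for binary gradings, and weighted kappa for the ordinal 4-point scale.

Kappa is ``(po - pe) / (1 - pe)`` where ``po`` is the observed agreement and
``pe`` the agreement expected from the marginal distributions alone. Weighted
kappa replaces exact agreement by agreement weights ``w_ij`` that credit
near-misses on an ordinal scale: linear (Cicchetti-Allison) weights
``1 - |i-j|/(k-1)`` or quadratic (Fleiss-Cohen) weights ``1 - (i-j)^2/(k-1)^2``.
Standard errors use the asymptotic variance of Fleiss, Cohen and Everitt; a
nonparametric bootstrap is available as a cross-check.
"""

from __future__ import annotations

import dataclasses
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "ContingencyTable",
    "KappaResult",
    "build_contingency",
    "percent_agreement",
    "cohen_kappa",
    "weighted_kappa",
    "bootstrap_kappa_ci",
    "interpret_kappa",
    "format_kappa",
]

WeightScheme = Literal["unweighted", "linear", "quadratic"]

# Interpretation ladder for interobserver kappa (upper bound inclusive).
_KAPPA_BANDS = (
    (0.20, "None"),
    (0.39, "Minimal"),
    (0.59, "Weak"),
    (0.79, "Moderate"),
    (0.90, "Strong"),
    (1.00, "Almost perfect"),
)


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """k x k cross-tabulation; rows = algorithm category, columns = reader."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or arr.shape[0] < 2:
            raise ValueError(f"counts must be square k x k with k >= 2, got {arr.shape}")
        if np.any(arr < 0) or not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValueError("counts must be nonnegative integers")
        arr = arr.astype(np.int64)
        if arr.sum() == 0:
            raise ValueError("contingency table is empty")
        object.__setattr__(self, "counts", arr)

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def proportions(self) -> np.ndarray:
        return self.counts / self.n


@dataclasses.dataclass(frozen=True)
class KappaResult:
    """A kappa estimate with its uncertainty and interpretation."""

    kappa: float
    po: float
    pe: float
    se: float
    ci95: tuple[float, float]
    percent_agreement: float
    scheme: WeightScheme
    label: str

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "po": self.po,
            "pe": self.pe,
            "se": self.se,
            "ci95": list(self.ci95),
            "percent_agreement": self.percent_agreement,
            "scheme": self.scheme,
            "label": self.label,
        }


def build_contingency(pairs: Iterable[tuple[int, int]], k: int) -> ContingencyTable:
    """Cross-tabulate (algorithm grade, reader grade) pairs on a 1..k scale."""
    counts = np.zeros((k, k), dtype=np.int64)
    n = 0
    for record, (a, r) in enumerate(pairs):
        if not (1 <= a <= k and 1 <= r <= k):
            raise ValueError(
                f"record {record}: grades ({a}, {r}) outside 1..{k}"
            )
        counts[a - 1, r - 1] += 1
        n += 1
    if n == 0:
        raise ValueError("no grade pairs supplied")
    return ContingencyTable(counts=counts)


def percent_agreement(t: ContingencyTable) -> float:
    """Observed agreement, uncorrected for chance: 100 * trace / n."""
    return 100.0 * float(np.trace(t.counts)) / t.n


def agreement_weights(k: int, scheme: WeightScheme) -> np.ndarray:
    """Agreement-weight matrix w_ij in [0, 1] with unit diagonal."""
    i, j = np.indices((k, k))
    if scheme == "unweighted":
        return (i == j).astype(float)
    d = np.abs(i - j) / (k - 1)
    if scheme == "linear":
        return 1.0 - d
    if scheme == "quadratic":
        return 1.0 - d**2
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def _kappa_core(t: ContingencyTable, scheme: WeightScheme) -> KappaResult:
    p = t.proportions()
    w = agreement_weights(t.k, scheme)
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.sum(w * p))
    pe = float(np.sum(w * np.outer(row, col)))
    if pe >= 1.0:
        raise ZeroDivisionError(
            "kappa undefined: chance agreement is 1 (all mass in one category)"
        )
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss-Cohen-Everitt asymptotic variance of the weighted kappa.
    wbar_row = w @ col      # average weight of row i against the column margin
    wbar_col = row @ w      # average weight of column j against the row margin
    term = w * (1.0 - pe) - (wbar_row[:, None] + wbar_col[None, :]) * (1.0 - po)
    var = (np.sum(p * term**2) - (po * pe - 2.0 * pe + po) ** 2) / (
        t.n * (1.0 - pe) ** 4
    )
    se = float(np.sqrt(max(var, 0.0)))
    ci = (kappa - 1.96 * se, kappa + 1.96 * se)
    return KappaResult(
        kappa=float(kappa),
        po=po,
        pe=pe,
        se=se,
        ci95=ci,
        percent_agreement=percent_agreement(t),
        scheme=scheme,
        label=interpret_kappa(kappa),
    )


def cohen_kappa(t: ContingencyTable) -> KappaResult:
    """Unweighted Cohen's kappa with Fleiss-Cohen-Everitt SE and 95% CI."""
    return _kappa_core(t, "unweighted")


def weighted_kappa(
    t: ContingencyTable, scheme: Literal["linear", "quadratic"] = "linear"
) -> KappaResult:
    """Weighted kappa for ordinal categories.

    Equivalent to ``1 - sum(d_ij o_ij) / sum(d_ij e_ij)`` with disagreement
    weights ``d = 1 - w`` and observed/expected cell proportions o, e. With
    k = 2 the linear scheme degenerates to unweighted kappa.
    """
    if scheme not in ("linear", "quadratic"):
        raise ValueError(f"scheme must be 'linear' or 'quadratic', got {scheme!r}")
    return _kappa_core(t, scheme)


def bootstrap_kappa_ci(
    t: ContingencyTable,
    scheme: WeightScheme = "unweighted",
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for kappa, resampling the n pairs."""
    rng = np.random.default_rng(seed)
    p = t.proportions().ravel()
    k = t.k
    stats = []
    for _ in range(n_boot):
        counts = rng.multinomial(t.n, p).reshape(k, k)
        try:
            stats.append(_kappa_core(ContingencyTable(counts), scheme).kappa)
        except ZeroDivisionError:
            continue  # degenerate resample: kappa undefined
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def interpret_kappa(kappa: float) -> str:
    """Band a kappa value on the interobserver-agreement ladder.

    Kappa is rounded half-up to 2 decimals first, which makes the bands
    exhaustive (.20 and .21 fall on opposite sides of the first cut).
    Negative values indicate worse-than-chance agreement and label "None".
    """
    if not (-1.0 - 1e-12 <= kappa <= 1.0 + 1e-12):
        raise ValueError(f"kappa out of [-1, 1]: {kappa}")
    k2 = float(Decimal(repr(float(kappa))).quantize(Decimal("0.01"), ROUND_HALF_UP))
    for upper, label in _KAPPA_BANDS:
        if k2 <= upper:
            return label
    return _KAPPA_BANDS[-1][1]


def format_kappa(kappa: float) -> str:
    """Render kappa to 2 decimals without a leading zero (e.g. '.10', '-.20')."""
    s = f"{kappa:.2f}"
    return s.replace("0.", ".", 1) if abs(kappa) < 1 else s
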