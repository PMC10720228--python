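"""Higher Criticism joint-hypothesis testing for rare-weak effects.

The HC statistic standardizes the deviation between the empirical c.d.f.
of a set of p-values and the uniform null at every order statistic and
takes the maximum over the lower ``alpha0`` fraction:

    HC = max_{i <= alpha0*N}  sqrt(N) * (i/N - p_(i)) / sqrt(p_(i) (1 - p_(i)))

Two published variants are provided: ``hc2004`` (the original) and
``hc_plus`` (the improved version, restricting to order statistics with
p_(i) > 1/N).  Significance is decided against a Monte-Carlo null computed
on uniform p-value samples of the same size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HCNull",
    "HCResult",
    "hc_statistic",
    "hc_null_distribution",
    "hc_test",
    "pvalue_histogram",
]

VARIANTS = ("hc2004", "hc_plus")


def _clip_bound(n: int) -> float:
    # Numerical guard only: never moves a p-value a test could produce.
    return min(1.0 / (10.0 * n), 1e-8)


def _hc_from_sorted(ps: np.ndarray, variant: str, alpha0: float) -> np.ndarray:
    """HC statistic row-wise from sorted p-values (2-D: replicates x N)."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if not (0.0 < alpha0 <= 1.0):
        raise ValueError("alpha0 must lie in (0, 1]")
    m, n = ps.shape
    bound = _clip_bound(n)
    p = np.clip(ps, bound, 1.0 - bound)
    i_over_n = np.arange(1, n + 1) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.sqrt(n) * (i_over_n - p) / np.sqrt(p * (1.0 - p))
    keep = int(np.floor(alpha0 * n))
    keep = max(keep, 1)
    terms = terms[:, :keep]
    if variant == "hc_plus":
        mask = p[:, :keep] > 1.0 / n
        restricted = np.where(mask, terms, -np.inf)
        out = restricted.max(axis=1)
        # Every order statistic excluded (all p <= 1/N) only happens under an
        # overwhelming signal; fall back to the unrestricted maximum there.
        empty = ~mask.any(axis=1)
        if empty.any():
            out[empty] = terms[empty].max(axis=1)
        return out
    return terms.max(axis=1)


def hc_statistic(pvalues: np.ndarray, variant: str = "hc_plus", alpha0: float = 0.5) -> float:
    """Higher Criticism statistic of one p-value set (can be negative)."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size < 2:
        raise ValueError("need at least 2 p-values")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return float(_hc_from_sorted(np.sort(p)[None, :], variant, alpha0)[0])


@dataclass
class HCNull:
    """Monte-Carlo null sample of HC values under uniform p-values."""

    n_pvalues: int
    variant: str
    alpha0: float
    values: np.ndarray  # sorted ascending
    seed: int | None = None

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.values, q))


@dataclass
class HCResult:
    """Outcome of one HC joint-hypothesis test."""

    n_pvalues: int
    variant: str
    alpha0: float
    hc_value: float
    null_quantile_95: float
    empirical_p: float
    reject: bool
    histogram_counts: list[int] = field(default_factory=list)
    first_bin_excess: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "n_pvalues": self.n_pvalues,
            "variant": self.variant,
            "alpha0": self.alpha0,
            "hc_value": self.hc_value,
            "null_quantile_95": self.null_quantile_95,
            "empirical_p": self.empirical_p,
            "reject": self.reject,
            "histogram_counts": list(self.histogram_counts),
            "first_bin_excess": self.first_bin_excess,
        }


def hc_null_distribution(
    n_pvalues: int,
    variant: str = "hc_plus",
    alpha0: float = 0.5,
    n_replicates: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> HCNull:
    """Empirical HC null: the statistic on ``n_replicates`` independent
    uniform(0,1) samples of size ``n_pvalues`` (chunked for memory)."""
    if n_replicates < 1000:
        raise ValueError("n_replicates must be >= 1000 for a usable null")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chunk = max(1, 4_000_000 // max(n_pvalues, 1))
    vals = np.empty(n_replicates)
    done = 0
    while done < n_replicates:
        m = min(chunk, n_replicates - done)
        u = rng.random((m, n_pvalues))
        u.sort(axis=1)
        vals[done : done + m] = _hc_from_sorted(u, variant, alpha0)
        done += m
    vals.sort()
    return HCNull(
        n_pvalues=n_pvalues,
        variant=variant,
        alpha0=alpha0,
        values=vals,
        seed=seed if isinstance(seed, int) else None,
    )


def hc_test(
    pvalues: np.ndarray,
    null: HCNull,
    alpha: float = 0.05,
    n_bins: int = 20,
) -> HCResult:
    """Test the joint null against a precomputed Monte-Carlo null.

    ``empirical_p = (1 + #{null >= observed}) / (M + 1)`` (add-one
    continuity); reject iff empirical_p <= alpha.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size != null.n_pvalues:
        raise ValueError(
            f"null was calibrated for N={null.n_pvalues}, got {p.size} p-values"
        )
    hc = hc_statistic(p, null.variant, null.alpha0)
    m = null.values.size
    n_ge = m - np.searchsorted(null.values, hc, side="left")
    emp_p = (1.0 + n_ge) / (m + 1.0)
    counts, excess = pvalue_histogram(p, n_bins)
    return HCResult(
        n_pvalues=p.size,
        variant=null.variant,
        alpha0=null.alpha0,
        hc_value=hc,
        null_quantile_95=null.quantile(0.95),
        empirical_p=float(emp_p),
        reject=bool(emp_p <= alpha),
        histogram_counts=counts.tolist(),
        first_bin_excess=excess,
    )


def pvalue_histogram(pvalues: np.ndarray, n_bins: int = 20) -> tuple[np.ndarray, float]:
    """Equal-width histogram of p-values on [0, 1].

    Returns ``(counts, first_bin_excess)`` where the excess ratio is the
    observed first-bin count over the uniform expectation N / n_bins — the
    plausibility diagnostic for an enrichment of low p-values.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    counts, _ = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    expected = p.size / n_bins
    excess = counts[0] / expected if expected > 0 else float("nan")
    return counts, float(excess)
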