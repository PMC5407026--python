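"""Hypothesis tests on allelic bursting: differential kinetics, imbalance,
independence, and FDR control.

The differential-kinetics test is a nonparametric bootstrap under the null
that both alleles share the same kinetic parameters: the 2n observed counts
are pooled, resampled with replacement, split back into two pseudo-alleles
(cell-size and depth factors stay attached to their cell slots), and the
kinetic estimator is re-run on each replicate.  The p-value is the fraction
of replicates whose absolute allelic difference in the statistic (burst
frequency k_on, or burst size s/k_off) reaches the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classify import CategoryCounts
from .containers import NoiseParams
from .kinetics import _moments_matrix, invert_moments

__all__ = [
    "BootstrapTestResult",
    "IndependenceTestResult",
    "bootstrap_differential_test",
    "binomial_imbalance_test",
    "independence_test",
    "fdr_adjust",
]


@dataclass
class BootstrapTestResult:
    observed_diff_freq: float
    observed_diff_size: float
    p_freq: float
    p_size: float
    n_boot: int
    n_valid_boot: int
    low_confidence: bool = False


@dataclass
class IndependenceTestResult:
    chi2: float
    p: float
    direction: str  # "coordinated", "repulsed", or "none"
    observed: tuple
    expected: tuple
    skipped: bool = False


def _pooled_split_moments(pool, idx, noise, phi):
    """Kinetics of one pseudo-allele built from resampled pool positions.

    ``idx`` is (n_boot, n) positions into the 2n pool of depth-normalised
    counts; the resampled value lands at cell slot j, so phi_j stays attached
    to the slot, not to the value.
    """
    m1, m2, m3 = _moments_matrix(pool[idx], noise, None, phi)
    return invert_moments(m1, m2, m3)


def bootstrap_differential_test(
    counts_a,
    counts_b,
    phi=None,
    noise: NoiseParams | None = None,
    eta=None,
    n_boot: int = 1000,
    seed=None,
) -> BootstrapTestResult:
    """Bootstrap test of equal allelic burst frequency and burst size.

    Replicates with non-estimable kinetics on either pseudo-allele are
    dropped from both numerator and denominator.  p-values are exceedance
    fractions, floored at 1/n_valid so they are never exactly 0; fewer than
    100 valid replicates sets ``low_confidence``.
    """
    if noise is None:
        noise = NoiseParams.identity()
    qa = np.asarray(counts_a, dtype=float)
    qb = np.asarray(counts_b, dtype=float)
    if qa.shape != qb.shape or qa.ndim != 1:
        raise ValueError("counts_a and counts_b must be equal-length vectors")
    n = qa.size
    phi_arr = None if phi is None else np.asarray(phi, dtype=float)
    if eta is not None:
        # depth correction belongs to the source cell; apply before pooling
        eta_arr = np.asarray(eta, dtype=float)
        qa = qa / eta_arr
        qb = qb / eta_arr

    obs = {}
    for name, q in (("A", qa), ("B", qb)):
        m1, m2, m3 = _moments_matrix(q[None, :], noise, None, phi_arr)
        k_on, k_off, s, ok = invert_moments(m1[0], m2[0], m3[0])
        if not ok:
            raise ValueError(
                f"allele {name} kinetics are not estimable at the observed "
                "data; the differential test requires estimable alleles"
            )
        obs[name] = (k_on, s / k_off)
    d_freq = abs(obs["A"][0] - obs["B"][0])
    d_size = abs(obs["A"][1] - obs["B"][1])

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # canonical (sorted) pool order: resampling is uniform over the multiset,
    # so sorting changes nothing statistically but makes the procedure exactly
    # invariant to swapping the allele labels
    pool = np.sort(np.concatenate([qa, qb]))
    draw = rng.integers(0, 2 * n, size=(n_boot, 2 * n))
    ka, koa, sa, oka = _pooled_split_moments(pool, draw[:, :n], noise, phi_arr)
    kb, kob, sb, okb = _pooled_split_moments(pool, draw[:, n:], noise, phi_arr)
    ok = oka & okb
    n_valid = int(ok.sum())
    if n_valid == 0:
        return BootstrapTestResult(d_freq, d_size, 1.0, 1.0, n_boot, 0, True)
    bd_freq = np.abs(ka[ok] - kb[ok])
    bd_size = np.abs(sa[ok] / koa[ok] - sb[ok] / kob[ok])
    p_freq = max(float(np.mean(bd_freq >= d_freq)), 1.0 / n_valid)
    p_size = max(float(np.mean(bd_size >= d_size)), 1.0 / n_valid)
    return BootstrapTestResult(
        observed_diff_freq=d_freq,
        observed_diff_size=d_size,
        p_freq=p_freq,
        p_size=p_size,
        n_boot=n_boot,
        n_valid_boot=n_valid,
        low_confidence=n_valid < 100,
    )


def binomial_imbalance_test(counts_a, counts_b) -> float:
    """Exact two-sided binomial test of mean allelic imbalance.

    Tests whether the A-allele share of the summed coverage across cells is
    0.5.  Returns the p-value; raises on zero total coverage.
    """
    ta = int(np.sum(counts_a))
    tb = int(np.sum(counts_b))
    if ta + tb == 0:
        raise ValueError("zero total coverage: imbalance test undefined")
    return float(stats.binomtest(ta, ta + tb, 0.5).pvalue)


def independence_test(counts: CategoryCounts, min_cells: int = 20) -> IndependenceTestResult:
    """Pearson chi-square test of independent allelic bursting.

    The (A expressed) x (B expressed) 2x2 table comes straight from the gene
    categorisation tallies; expected counts derive from the marginal
    expressed fractions.  Direction is "coordinated" when more cells express
    both alleles than independence predicts, "repulsed" when fewer.  Genes
    with degenerate marginals or fewer than ``min_cells`` assignable cells
    are skipped.
    """
    ne, na, nb, nab = counts.as_tuple()
    n = ne + na + nb + nab
    if n < min_cells:
        return IndependenceTestResult(
            np.nan, np.nan, "none", (ne, na, nb, nab), (np.nan,) * 4, skipped=True
        )
    p_a = (na + nab) / n
    p_b = (nb + nab) / n
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return IndependenceTestResult(
            np.nan, np.nan, "none", (ne, na, nb, nab), (np.nan,) * 4, skipped=True
        )
    expected = (
        n * (1 - p_a) * (1 - p_b),
        n * p_a * (1 - p_b),
        n * (1 - p_a) * p_b,
        n * p_a * p_b,
    )
    observed = (ne, na, nb, nab)
    chi2 = float(sum((o - e) ** 2 / e for o, e in zip(observed, expected)))
    p = float(stats.chi2.sf(chi2, df=1))
    if nab > expected[3]:
        direction = "coordinated"
    elif nab < expected[3]:
        direction = "repulsed"
    else:
        direction = "none"
    return IndependenceTestResult(chi2, p, direction, observed, expected)


def fdr_adjust(p, alpha: float = 0.05):
    """Benjamini-Hochberg step-up; returns (q_values, significant_flags).

    NaN p-values (skipped tests) pass through as NaN and are never flagged.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    flags = np.zeros(p.shape, dtype=bool)
    valid = np.isfinite(p)
    if np.any(valid):
        rej, qv, _, _ = multipletests(p[valid], alpha=alpha, method="fdr_bh")
        q[valid] = qv
        flags[valid] = rej
    return q, flags
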