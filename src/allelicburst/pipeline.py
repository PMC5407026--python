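"""End-to-end pipeline: normalise, fit noise, classify, estimate, test.

``AllelicBurstingPipeline`` composes the per-module estimators into the full
workflow: library-size factors, spike-in noise fitting (identity fallback with
a warning when no spike-ins are supplied), cell-size factors, per-gene
state classification, kinetics for biallelic bursty genes, the three test
families, and per-family Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import normalize
from .classify import AllelicStateClassifier
from .containers import AllelicCountMatrix, NoiseParams, SpikeInSet
from .hypothesis_tests import (
    binomial_imbalance_test,
    bootstrap_differential_test,
    fdr_adjust,
    independence_test,
)
from .kinetics import estimate_allele_kinetics
from .technoise import TechnicalNoiseModel

logger = logging.getLogger(__name__)

__all__ = ["AllelicBurstingPipeline", "run_scale"]

_KIN_COLS = [
    "k_on", "k_off", "s", "burst_frequency", "burst_size",
    "burst_frequency_se", "burst_size_se",
]


class AllelicBurstingPipeline(BaseEstimator):
    """Full allele-specific bursting analysis as one sklearn-style estimator.

    Parameters mirror the CLI flags.  ``noise`` may be given directly to skip
    spike-in fitting.  ``n_boot`` drives the differential tests; ``n_boot_se``
    the kinetic standard errors.

    Attributes (after ``fit``)
    --------------------------
    results_ : pandas.DataFrame, one row per input gene.
    noise_ : NoiseParams used for deconvolution.
    eta_, phi_ : per-cell library-size and cell-size factors.
    """

    def __init__(
        self,
        epsilon: float = 1e-3,
        min_posterior: float = 0.8,
        bursty_low: float = 0.05,
        bursty_high: float = 0.95,
        n_boot: int = 1000,
        n_boot_se: int = 200,
        fdr_alpha: float = 0.05,
        noise: NoiseParams | None = None,
        random_state: int | None = None,
    ):
        self.epsilon = epsilon
        self.min_posterior = min_posterior
        self.bursty_low = bursty_low
        self.bursty_high = bursty_high
        self.n_boot = n_boot
        self.n_boot_se = n_boot_se
        self.fdr_alpha = fdr_alpha
        self.noise = noise
        self.random_state = random_state

    # -- stages ---------------------------------------------------------
    def _fit_noise(self, spikes: SpikeInSet | None, eta) -> NoiseParams:
        if self.noise is not None:
            return self.noise
        if spikes is None:
            warnings.warn(
                "no spike-ins and no noise parameters supplied: technical "
                "noise is assumed absent (identity model)",
                UserWarning,
            )
            return NoiseParams.identity()
        truth = normalize.spike_in_true_molecules(spikes)
        observed = normalize.spike_in_observed_molecules(spikes, eta)
        keep = truth > 0
        model = TechnicalNoiseModel().fit(truth[keep], observed[keep])
        logger.info(
            "fitted noise parameters: alpha=%.4g beta=%.4g kappa=%.4g tau=%.4g",
            model.alpha_, model.beta_, model.kappa_, model.tau_,
        )
        return model.to_noise_params()

    def fit(self, counts: AllelicCountMatrix, spikes: SpikeInSet | None = None,
            cell_sizes=None):
        """Run the full pipeline on an allelic count matrix."""
        root = np.random.SeedSequence(self.random_state)
        gene_seeds = root.spawn(counts.n_genes)

        try:
            eta = normalize.library_size_factors(counts)
        except ValueError:
            warnings.warn(
                "library-size factors undefined (every gene has a zero-total "
                "cell); proceeding with eta = 1",
                UserWarning,
            )
            eta = np.ones(counts.n_cells)
        self.eta_ = eta
        self.noise_ = self._fit_noise(spikes, eta)
        self.phi_ = normalize.cell_size_factors(counts, spikes, user_phi=cell_sizes)

        rows = []
        for g in range(counts.n_genes):
            row = self._fit_gene(
                counts.genes[g], counts.Q_A[g], counts.Q_B[g], gene_seeds[g]
            )
            rows.append(row)
        results = pd.DataFrame(rows)

        # per-family FDR across genes
        for test in ("p_diff_frequency", "p_diff_size", "p_imbalance",
                     "p_independence"):
            qcol = test.replace("p_", "q_")
            q, flags = fdr_adjust(results[test].to_numpy(), self.fdr_alpha)
            results[qcol] = q
            results[qcol.replace("q_", "sig_")] = flags
        # direction is interpreted only where the independence test survives FDR
        results["independence_direction"] = np.where(
            results["sig_independence"], results["_direction"], "none"
        )
        results = results.drop(columns=["_direction"])
        self.results_ = results
        counts_by_cat = results["category"].value_counts().to_dict()
        logger.info("gene categories: %s", counts_by_cat)
        return self

    def _fit_gene(self, gene, q_a, q_b, seed_seq) -> dict:
        row = {"gene": gene, "category": "unclassifiable", "estimable": False,
               "unstable": False,
               "N_empty": 0, "N_A": 0, "N_B": 0, "N_AB": 0, "n_unassigned": 0}
        for col in _KIN_COLS:
            row[f"{col}_A"] = np.nan
            row[f"{col}_B"] = np.nan
        for col in ("p_diff_frequency", "p_diff_size", "p_imbalance",
                    "p_independence"):
            row[col] = np.nan
        row["_direction"] = "none"
        try:
            clf = AllelicStateClassifier(
                epsilon=self.epsilon,
                min_posterior=self.min_posterior,
                bursty_low=self.bursty_low,
                bursty_high=self.bursty_high,
            ).fit(q_a, q_b)
            category, cc = clf.gene_category()
            row["category"] = category
            row.update(
                N_empty=cc.N_empty, N_A=cc.N_A, N_B=cc.N_B, N_AB=cc.N_AB,
                n_unassigned=cc.n_unassigned,
            )
            if category != "biallelic_bursty":
                return row

            rng = np.random.default_rng(seed_seq)
            est = estimate_allele_kinetics(
                q_a, q_b, noise=self.noise_, eta=self.eta_, phi=self.phi_,
                n_boot=self.n_boot_se, seed=rng,
            )
            for allele in ("A", "B"):
                e = est[allele]
                if e.estimable:
                    row[f"k_on_{allele}"] = e.k_on
                    row[f"k_off_{allele}"] = e.k_off
                    row[f"s_{allele}"] = e.s
                    row[f"burst_frequency_{allele}"] = e.burst_frequency
                    row[f"burst_size_{allele}"] = e.burst_size
                    row[f"burst_frequency_se_{allele}"] = e.se.get(
                        "burst_frequency", np.nan
                    )
                    row[f"burst_size_se_{allele}"] = e.se.get("burst_size", np.nan)
            row["estimable"] = est["A"].estimable and est["B"].estimable
            row["unstable"] = est["A"].unstable or est["B"].unstable

            if q_a.sum() + q_b.sum() > 0:
                row["p_imbalance"] = binomial_imbalance_test(q_a, q_b)
            ind = independence_test(cc)
            if not ind.skipped:
                row["p_independence"] = ind.p
                row["_direction"] = ind.direction
            if row["estimable"]:
                bt = bootstrap_differential_test(
                    q_a, q_b, phi=self.phi_, noise=self.noise_, eta=self.eta_,
                    n_boot=self.n_boot, seed=rng,
                )
                row["p_diff_frequency"] = bt.p_freq
                row["p_diff_size"] = bt.p_size
        except Exception as exc:  # gene-level isolation: one bad gene cannot
            # take down the run
            logger.warning("gene %s failed: %s", gene, exc)
        return row


def run_scale(
    counts: AllelicCountMatrix,
    spikes: SpikeInSet | None = None,
    cell_sizes=None,
    **params,
) -> pd.DataFrame:
    """One-call pipeline; returns the per-gene results table."""
    pipe = AllelicBurstingPipeline(**params).fit(counts, spikes, cell_sizes)
    return pipe.results_
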