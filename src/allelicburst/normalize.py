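"""Library-size factors, spike-in molecule conversion, and cell-size factors."""

from __future__ import annotations

import warnings

import numpy as np

from .containers import AVOGADRO, AllelicCountMatrix, SpikeInSet

__all__ = [
    "library_size_factors",
    "spike_in_true_molecules",
    "spike_in_observed_molecules",
    "cell_size_factors",
]


def library_size_factors(counts: AllelicCountMatrix) -> np.ndarray:
    """Median-of-ratios library-size factor eta_c per cell.

    eta_c = median over genes of (Q_A + Q_B) / geometric-mean over cells of
    that gene's total.  Genes whose total is zero in any cell are excluded
    (their geometric mean is undefined).
    """
    total = counts.total().astype(float)
    usable = np.all(total > 0, axis=1)
    if not np.any(usable):
        raise ValueError(
            "no gene has non-zero total counts in every cell; "
            "library-size factors are undefined"
        )
    t = total[usable]
    log_gm = np.mean(np.log(t), axis=1, keepdims=True)
    eta = np.median(t / np.exp(log_gm), axis=0)
    return eta


def spike_in_true_molecules(spikes: SpikeInSet) -> np.ndarray:
    """True molecule count per spike-in per uL of lysis volume.

    molecules = C * 1e-18 mol/uL * Avogadro / dilution_factor, with C the
    pre-dilution concentration in attomoles/uL.  Zero-concentration spike-ins
    yield 0 molecules and are flagged for exclusion downstream.
    """
    conc = spikes.concentration
    if np.any(conc == 0):
        warnings.warn(
            "spike-in(s) with zero concentration excluded from noise fitting",
            UserWarning,
        )
    return conc * 1e-18 * AVOGADRO / spikes.dilution_factor


def spike_in_observed_molecules(
    spikes: SpikeInSet, eta: np.ndarray | None = None
) -> np.ndarray:
    """Convert observed spike-in reads to molecule-equivalents per cell.

    observed_molecules = reads * read_length / molecule_length / eta_c:
    reads are turned into transcript-equivalents by the length ratio, then
    depth-normalised by the library-size factor.
    """
    if np.any(spikes.molecule_length < spikes.read_length):
        warnings.warn(
            "spike-in shorter than the read length; molecule conversion "
            "will exceed the raw read count",
            UserWarning,
        )
    out = spikes.observed_reads * spikes.read_length / spikes.molecule_length[:, None]
    if eta is not None:
        eta = np.asarray(eta, dtype=float)
        if eta.size != out.shape[1]:
            raise ValueError("eta must have one entry per cell")
        out = out / eta[None, :]
    return out


def cell_size_factors(
    counts: AllelicCountMatrix,
    spikes: SpikeInSet | None = None,
    user_phi: np.ndarray | None = None,
) -> np.ndarray:
    """Cell-size factor phi_c, median-normalised to 1.

    The endogenous-to-spike-in read ratio proxies total mRNA content: cells
    with more endogenous reads per spike-in read are larger.  A user-supplied
    phi bypasses the proxy and is only median-normalised.  Cells with zero
    spike-in reads get phi = 1 with a warning.
    """
    if user_phi is not None:
        phi = np.asarray(user_phi, dtype=float).copy()
        if phi.size != counts.n_cells:
            raise ValueError("user phi must have one entry per cell")
        if np.any(phi <= 0):
            raise ValueError("cell sizes must be strictly positive")
        return phi / np.median(phi)
    if spikes is None:
        return np.ones(counts.n_cells)
    if spikes.n_cells != counts.n_cells:
        raise ValueError("spike-in table and count matrix disagree on cells")
    endo = counts.total().sum(axis=0).astype(float)
    spike = spikes.observed_reads.sum(axis=0).astype(float)
    bad = (spike == 0) | (endo == 0)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} cell(s) have zero spike-in or zero endogenous "
            "reads; their size factor is set to 1",
            UserWarning,
        )
    raw = np.where(bad, np.nan, endo / np.where(bad, 1.0, spike))
    med = np.nanmedian(raw)
    phi = raw / med
    phi[bad] = 1.0
    return phi
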