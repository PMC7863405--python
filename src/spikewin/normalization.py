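"""Spike-in anchored normalization: RUV-style unwanted-variation factors from
lambda control features, library-size offsets, the PC1 batch covariate, and
spike-in QC ratios.

Lambda windows are the control "genes": because lambda is added before
transposition it absorbs the same per-sample technical variation as the host
counts, so factors estimated from lambda alone can be put into the GLM design
to soak up that variation without touching the biology.  phiX is added after
transposition and is used for QC only, never as a normalization control.

All log transforms use a 0.5 pseudo-count.  Factor signs are fixed so the
largest-magnitude element of each factor column is positive, making outputs
deterministic across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .window_counting import CountMatrix

PSEUDOCOUNT = 0.5

OFFSET_MODES = ("library_size", "ruv", "combined")


@dataclass
class ControlSet:
    """Row indices of a CountMatrix used as negative-control features."""

    control_rows: np.ndarray  # lambda rows: RUV controls
    qc_rows: np.ndarray  # phiX rows: QC only

    def __post_init__(self) -> None:
        if len(self.control_rows) == 0:
            raise ValueError("control set must be non-empty")


@dataclass
class UnwantedFactors:
    """Sample-side factor scores for unwanted technical variation."""

    W: np.ndarray  # samples x k, unit-norm columns
    k: int
    explained_variance: np.ndarray  # fraction per factor (diagnostic)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class SampleOffsets:
    """Per-sample log-scale offsets for the GLM, with provenance.

    Offsets are always the host library-size logs; when ``mode`` is ``ruv``
    or ``combined`` the estimated factors additionally enter the GLM design
    as covariates (``use_ruv_covariates``).
    """

    samples: list[str]
    log_library: np.ndarray
    mode: str
    use_ruv_covariates: bool

    def per_row(self, n_rows: int) -> np.ndarray:
        """Offsets broadcast to (n_rows, n_samples)."""
        return np.broadcast_to(self.log_library, (n_rows, len(self.samples)))


@dataclass
class SpikeQC:
    samples: list[str]
    lambda_fraction: np.ndarray
    phiX_fraction: np.ndarray | None
    duplicate_fraction: np.ndarray | None = None


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Flip so the largest-magnitude element is positive (deterministic)."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def build_spike_controls(
    count_matrix: CountMatrix, lambda_contig: str = "lambda", phix_contig: str = "phiX"
) -> ControlSet:
    """Flag lambda rows as RUV controls and phiX rows for QC."""
    lam = np.flatnonzero(count_matrix.chroms == lambda_contig)
    phix = np.flatnonzero(count_matrix.chroms == phix_contig)
    if len(lam) == 0:
        raise ValueError(f"no rows on lambda contig {lambda_contig!r}")
    return ControlSet(control_rows=lam, qc_rows=phix)


def estimate_ruv_factors(
    count_matrix: CountMatrix, controls: ControlSet, k: int = 1
) -> UnwantedFactors:
    """Estimate k unwanted-variation factors from control-feature counts.

    log(count+0.5) on control rows is centered per row across samples; the
    first k left singular directions of the resulting samples x controls
    matrix are the factor scores.
    """
    n_samples = count_matrix.n_samples
    if k >= n_samples:
        raise ValueError(f"k={k} must be < n_samples={n_samples}")
    if k > len(controls.control_rows):
        raise ValueError("need at least k control rows")
    logc = np.log(count_matrix.counts[controls.control_rows].astype(float) + PSEUDOCOUNT)
    centered = logc - logc.mean(axis=1, keepdims=True)  # center each control row
    if not np.any(np.abs(centered) > 1e-12):
        raise ValueError("control features show no variation across samples")
    # samples x controls orientation; left singular vectors are sample scores
    U, s, _ = np.linalg.svd(centered.T, full_matrices=False)
    W = np.column_stack([_fix_sign(U[:, i]) for i in range(k)])
    ev = (s**2) / np.sum(s**2)
    return UnwantedFactors(W=W, k=k, explained_variance=ev[:k])


def compute_offsets(
    count_matrix: CountMatrix,
    factors: UnwantedFactors | None = None,
    mode: str = "library_size",
) -> SampleOffsets:
    """Library-size offsets plus a flag recording the RUV covariate path."""
    if mode not in OFFSET_MODES:
        raise ValueError(f"mode must be one of {OFFSET_MODES}")
    totals = count_matrix.host_library_sizes().astype(float)
    if np.any(totals <= 0):
        bad = [s for s, t in zip(count_matrix.samples, totals) if t <= 0]
        raise ValueError(f"zero host counts for sample(s) {bad}")
    use_ruv = mode in ("ruv", "combined")
    if use_ruv and factors is None:
        raise ValueError(f"mode={mode!r} requires estimated factors")
    return SampleOffsets(
        samples=list(count_matrix.samples),
        log_library=np.log(totals),
        mode=mode,
        use_ruv_covariates=use_ruv,
    )


def compute_pc1_covariate(count_matrix: CountMatrix) -> np.ndarray:
    """PC1 score per sample from log host counts, for batch adjustment.

    PCA treats samples as observations of the centered log(count+0.5)
    matrix over host (retained, if flagged) windows.  Scores are centered at
    zero; the sign convention matches the factor convention.
    """
    if count_matrix.n_samples < 3:
        raise ValueError("PC1 covariate needs >= 3 samples")
    host = ~count_matrix.is_spike
    if count_matrix.retained is not None:
        host = host & count_matrix.retained
    logc = np.log(count_matrix.counts[host].astype(float) + PSEUDOCOUNT)
    X = logc.T  # samples x windows
    X = X - X.mean(axis=0, keepdims=True)
    if not np.any(np.abs(X) > 1e-12):
        raise ValueError("no variance across samples; PC1 undefined")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = _fix_sign(U[:, 0] * s[0])
    return scores - scores.mean()


def spike_qc(
    count_matrix: CountMatrix,
    lambda_contig: str = "lambda",
    phix_contig: str = "phiX",
    duplicate_fraction: np.ndarray | None = None,
) -> SpikeQC:
    """Per-sample spike ratios; warns when lambda fraction varies > 5x."""
    host = count_matrix.host_library_sizes().astype(float)
    lam = count_matrix.spike_total(lambda_contig).astype(float)
    lam_frac = np.divide(lam, host, out=np.zeros_like(lam), where=host > 0)
    phix_frac = None
    if np.any(count_matrix.chroms == phix_contig):
        phix = count_matrix.spike_total(phix_contig).astype(float)
        phix_frac = np.divide(phix, host, out=np.zeros_like(phix), where=host > 0)
    pos = lam_frac[lam_frac > 0]
    if len(pos) >= 2 and pos.max() / pos.min() > 5:
        warnings.warn(
            f"lambda spike fraction varies {pos.max() / pos.min():.1f}-fold "
            "across samples (> 5x): check spike-in handling"
        )
    return SpikeQC(
        samples=list(count_matrix.samples),
        lambda_fraction=lam_frac,
        phiX_fraction=phix_frac,
        duplicate_fraction=duplicate_fraction,
    )
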