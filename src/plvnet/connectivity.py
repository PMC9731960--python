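"""Phase-locking value (PLV) connectivity matrices.

The PLV between two phase series phi_i, phi_j over T samples is the modulus
of the circular mean of the phase difference::

    PLV = | (1/T) * sum_t exp(1j * (phi_i(t) - phi_j(t))) |

It is 1 for a constant phase lag, 0 for perfectly balanced antiphase
segments, and approaches the Rayleigh chance level sqrt(pi / (4*T)) in
expectation for T independent uniform phases.  PLV depends on phase only,
so it is invariant to any positive rescaling of the underlying signals.

Per epoch a full symmetric matrix is computed for all region pairs; the
subject-level matrix is the arithmetic mean of the per-epoch matrices over
kept epochs (epoch-wise PLV first, averaging second — not sample pooling).
The diagonal is set to 1 by convention and excluded from every statistical
family downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import PhaseTensor


class ConnectivityError(ValueError):
    pass


@dataclass
class PLVMatrixSet:
    """Per-band symmetric n_roi x n_roi epoch-averaged PLV matrices."""

    matrices: dict[str, np.ndarray]
    n_epochs_used: int
    subject_id: str = ""
    roi_labels: list[str] = field(default_factory=list)

    @property
    def n_rois(self) -> int:
        return next(iter(self.matrices.values())).shape[0]

    def validate(self) -> None:
        for name, m in self.matrices.items():
            if m.shape[0] != m.shape[1]:
                raise ConnectivityError(f"band {name}: matrix not square")
            if not np.allclose(m, m.T):
                raise ConnectivityError(f"band {name}: matrix not symmetric")
            if (m < -1e-9).any() or (m > 1 + 1e-9).any():
                raise ConnectivityError(f"band {name}: PLV outside [0, 1]")


def plv_epoch(phase_i: np.ndarray, phase_j: np.ndarray) -> float:
    """PLV between two equal-length phase series of one epoch."""
    phase_i = np.asarray(phase_i, dtype=float)
    phase_j = np.asarray(phase_j, dtype=float)
    if phase_i.shape != phase_j.shape:
        raise ConnectivityError(
            f"phase series length mismatch: {phase_i.shape} vs {phase_j.shape}"
        )
    if phase_i.size < 2:
        raise ConnectivityError("need at least 2 phase samples")
    if not (np.all(np.isfinite(phase_i)) and np.all(np.isfinite(phase_j))):
        raise ConnectivityError("non-finite phase values")
    return float(np.abs(np.exp(1j * (phase_i - phase_j)).mean()))


def _plv_matrices_one_band(phases: np.ndarray, trim: int) -> np.ndarray:
    """Per-epoch PLV matrices for one band.

    phases: (n_epochs, n_rois, n_samples).  Uses the identity
    PLV_ij = |(Z Z^H)/T|_ij with Z = exp(1j*phi) restricted to the kept
    (trimmed) sample window, one matrix product per epoch.
    """
    if trim > 0:
        phases = phases[..., trim:-trim]
    n_samples = phases.shape[-1]
    if n_samples < 2:
        raise ConnectivityError("fewer than 2 samples per epoch after trimming")
    z = np.exp(1j * phases)
    # (n_epochs, n_rois, n_rois); zgemm per epoch
    cross = np.matmul(z, z.conj().transpose(0, 2, 1)) / n_samples
    return np.abs(cross)


def plv_subject(
    phases: PhaseTensor,
    edge_trim: int | None = None,
    subject_id: str = "",
) -> PLVMatrixSet:
    """Epoch-averaged PLV matrices for one subject, all bands.

    Each unordered pair is computed once per epoch; per-epoch matrices are
    averaged arithmetically over kept epochs.  Symmetry is exact by
    construction and the diagonal is set to 1.
    """
    trim = phases.edge_trim if edge_trim is None else int(edge_trim)
    matrices: dict[str, np.ndarray] = {}
    n_epochs = None
    for name, tensor in phases.phases.items():
        if tensor.shape[0] == 0:
            raise ConnectivityError("zero epochs: PLV undefined")
        n_epochs = tensor.shape[0]
        per_epoch = _plv_matrices_one_band(tensor, trim)
        mean = per_epoch.mean(axis=0)
        mean = 0.5 * (mean + mean.T)  # exact symmetry against rounding
        np.fill_diagonal(mean, 1.0)
        matrices[name] = np.clip(mean, 0.0, 1.0)
    return PLVMatrixSet(
        matrices,
        n_epochs_used=int(n_epochs or 0),
        subject_id=subject_id,
        roi_labels=list(phases.channel_labels),
    )


def plv_long_table(plv_sets: dict[str, PLVMatrixSet], roi_labels: list[str]):
    """Long-format table (subject, band, roi_a, roi_b, plv) for all pairs."""
    import pandas as pd

    rows = []
    for subject, pset in plv_sets.items():
        for band, m in pset.matrices.items():
            n = m.shape[0]
            for i in range(n):
                for j in range(i + 1, n):
                    rows.append((subject, band, roi_labels[i], roi_labels[j], m[i, j]))
    return pd.DataFrame(rows, columns=["subject", "band", "roi_a", "roi_b", "plv"])
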