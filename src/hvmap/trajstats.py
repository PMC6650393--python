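"""Per-lobe RMSD time series and per-residue RMSF over an ensemble.

Both statistics are Cα-based and computed after least-squares superposition
on the selection itself, so each lobe is analysed in its own fitted frame
(inter-lobe motion does not leak into the numbers).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import kabsch_superpose
from .structures import Model, ResidueRange, StructureEnsemble, select_ca

__all__ = ["RmsdSeries", "RmsfProfile", "rmsd_series", "rmsf_profile",
           "write_rmsd_tsv", "write_rmsf_tsv"]


@dataclass
class RmsdSeries:
    """Cα RMSD per frame versus a reference model, after superposition."""

    values: np.ndarray  # Å, one per frame
    selection: list[ResidueRange]
    run_id: str = ""


@dataclass
class RmsfProfile:
    """Cα RMSF per residue about the superposed ensemble mean."""

    residues: list[int]
    values: np.ndarray  # Å, one per residue
    selection: list[ResidueRange]
    run_id: str = ""


def _selection_ca(model: Model, selection: Sequence[ResidueRange]) -> np.ndarray:
    if not selection:
        raise ValueError("empty selection")
    return np.vstack([select_ca(model, rng) for rng in selection])


def rmsd_series(
    ensemble: StructureEnsemble,
    reference_model: Model,
    selection: Sequence[ResidueRange],
    run_id: str = "",
) -> RmsdSeries:
    """Per-frame RMSD from a reference after fitting on the selection Cα."""
    ref = _selection_ca(reference_model, selection)
    vals = np.array(
        [kabsch_superpose(_selection_ca(m, selection), ref).rmsd for m in ensemble]
    )
    return RmsdSeries(values=vals, selection=list(selection),
                      run_id=run_id or ensemble.source_id)


def rmsf_profile(
    ensemble: StructureEnsemble,
    selection: Sequence[ResidueRange],
    run_id: str = "",
) -> RmsfProfile:
    """Per-residue fluctuation about the ensemble mean structure.

    Two-pass superposition: every frame is fitted to the first model, the
    mean structure is computed, every frame is re-fitted to that mean, and
    RMSF_i = sqrt(mean over frames of |x_i − <x_i>|²).
    """
    if len(ensemble) < 2:
        raise ValueError("RMSF needs at least 2 models")
    coords = np.stack([_selection_ca(m, selection) for m in ensemble])
    fitted = np.stack(
        [kabsch_superpose(c, coords[0]).apply(c) for c in coords]
    )
    mean1 = fitted.mean(axis=0)
    refit = np.stack([kabsch_superpose(c, mean1).apply(c) for c in coords])
    mean2 = refit.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((refit - mean2) ** 2, axis=2), axis=0))
    residues = [r for rng in selection for r in rng.residues()]
    return RmsfProfile(residues=residues, values=rmsf,
                       selection=list(selection), run_id=run_id or ensemble.source_id)


def write_rmsd_tsv(series: RmsdSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(series.values)), "rmsd": series.values}
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_rmsf_tsv(profile: RmsfProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"residue": profile.residues, "rmsf": profile.values}
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")
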