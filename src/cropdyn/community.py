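"""Weed-community analysis: diversity indices, Hellinger standardization,
rare-species filtering, and index-species correlation screening.

Indices follow the conventions of the BiodiversityR/vegan family, with the
Shannon index in natural-log units (nats) so that E-evenness = exp(H)/S and
the inverse Simpson index ranges from 1 to S:

    p_i        = biomass share of species i
    S          = richness (species with biomass > 0)
    H          = -sum p_i ln p_i            (Shannon-Wiener)
    D          = 1 - sum p_i^2              (Simpson)
    invsimpson = 1 / sum p_i^2              (effective species number)
    J          = H / ln S  (0 when S = 1)   (Pielou J-evenness)
    E          = exp(H) / S                 (E-evenness)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiversityIndices",
    "diversity_indices",
    "diversity_table",
    "community_matrix",
    "hellinger",
    "filter_rare",
    "correlation_screen",
    "INDEX_NAMES",
]

INDEX_NAMES = ("richness", "shannon", "simpson", "invsimpson", "Jevenness", "Eevenness")


@dataclass(frozen=True)
class DiversityIndices:
    richness: int
    shannon: float
    simpson: float
    invsimpson: float
    Jevenness: float
    Eevenness: float


def community_matrix(weeds: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long weeds table into a sample x species biomass matrix.

    Rows are indexed by (year, treatment, replicate); missing species get 0.
    """
    for col in ("year", "treatment", "replicate", "species_code", "biomass_g_m2"):
        if col not in weeds.columns:
            raise ValueError(f"weeds table: missing required column {col!r}")
    mat = weeds.pivot_table(
        index=["year", "treatment", "replicate"],
        columns="species_code",
        values="biomass_g_m2",
        aggfunc="sum",
        fill_value=0.0,
    )
    mat.columns.name = None
    return mat


def diversity_indices(biomass) -> DiversityIndices:
    """Diversity indices of a single sample's biomass vector."""
    x = np.asarray(biomass, dtype=float)
    if np.any(x < 0):
        raise ValueError("biomass values must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero biomass vector: no community")
    p = x[x > 0] / total
    S = p.size
    H = float(-(p * np.log(p)).sum())
    sum_p2 = float((p**2).sum())
    return DiversityIndices(
        richness=int(S),
        shannon=H,
        simpson=1.0 - sum_p2,
        invsimpson=1.0 / sum_p2,
        Jevenness=0.0 if S == 1 else H / np.log(S),
        Eevenness=float(np.exp(H) / S),
    )


def diversity_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample diversity indices of a community matrix (one row per sample)."""
    rows = {}
    for key, row in matrix.iterrows():
        d = diversity_indices(row.to_numpy(float))
        rows[key] = {name: getattr(d, name) for name in INDEX_NAMES}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=matrix.index.names) \
        if isinstance(matrix.index, pd.MultiIndex) else out.index
    return out


def hellinger(matrix: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: cell' = sqrt(cell / row_sum).

    Each nonzero row of the result has unit sum of squares.  All-zero rows are
    passed through as zeros with a warning.
    """
    vals = matrix.to_numpy(float)
    if np.any(vals < 0):
        raise ValueError("negative abundance in community matrix")
    sums = vals.sum(axis=1, keepdims=True)
    zero = sums[:, 0] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero sample row(s) passed through as zeros")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(np.where(sums > 0, vals / np.where(sums == 0, 1.0, sums), 0.0))
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def filter_rare(matrix: pd.DataFrame, occupancy_threshold: float = 0.05):
    """Drop species occupying at most `occupancy_threshold` of samples.

    A species' occupancy is the fraction of samples where its biomass is
    positive; species at or below the threshold are removed.  Returns the
    reduced matrix and the list of removed species codes.
    """
    if not 0 < occupancy_threshold < 1:
        raise ValueError("occupancy threshold must be in (0, 1)")
    occ = (matrix > 0).mean(axis=0)
    removed = list(matrix.columns[occ <= occupancy_threshold])
    kept = matrix.drop(columns=removed)
    if kept.shape[1] == 0:
        warnings.warn("rare-species filter removed every species")
    return kept, removed


def correlation_screen(
    indices: pd.DataFrame, species: pd.DataFrame, threshold: float = 0.4
) -> pd.DataFrame:
    """Pearson correlations between diversity indices and (Hellinger-
    transformed) species abundances, keeping pairs with |r| > threshold.

    No p-values are attached: the indices are computed from the same species
    data, so the pairs are not independent.  Zero-variance columns are
    skipped with a warning.  Output is sorted by |r| descending.
    """
    common = indices.index.intersection(species.index)
    if len(common) < 3:
        raise ValueError("need at least 3 matching samples for a correlation screen")
    A = indices.loc[common]
    B = species.loc[common]
    rows = []
    for ind in A.columns:
        x = A[ind].to_numpy(float)
        if np.std(x) == 0:
            warnings.warn(f"index {ind!r} has zero variance; skipped")
            continue
        for sp in B.columns:
            y = B[sp].to_numpy(float)
            if np.std(y) == 0:
                warnings.warn(f"species {sp!r} has zero variance; skipped")
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            if abs(r) > threshold:
                rows.append({"index": ind, "species": sp, "r": r})
    out = pd.DataFrame(rows, columns=["index", "species", "r"])
    if len(out):
        out = out.reindex(out["r"].abs().sort_values(ascending=False).index)
        out = out.reset_index(drop=True)
    return out
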