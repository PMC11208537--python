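"""Alpha diversity, Bray-Curtis dissimilarity and NMDS ordination.

Alpha-diversity estimators follow the QIIME 1.9 conventions: Shannon in
bits (log base 2), bias-corrected Chao1, ACE with rare-abundance cutoff
10, and Good's coverage ``1 - F1/N``.  Counts are used as loaded — no
rarefaction — with sequencing depth logged per sample.

Beta diversity is Bray-Curtis on raw counts; ordination is non-metric
MDS (Kruskal stress-1, monotone regression) with seeded restarts.  The
sign of an NMDS axis is statistically arbitrary; NMDS1 is canonicalised
so that its Pearson correlation with the rank of sample read depth is
non-negative (only squared quantities consume the axis downstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, rankdata
from skbio import DistanceMatrix
from skbio.diversity import alpha as _alpha
from sklearn.manifold import MDS

from .tables_io import OTUTable

logger = logging.getLogger(__name__)


@dataclass
class DiversityProfile:
    sample_id: str
    sobs: int
    chao1: float
    ace: float
    shannon: float  # bits
    coverage: float

    def __post_init__(self) -> None:
        assert self.chao1 >= self.sobs - 1e-9
        assert 0.0 <= self.coverage <= 1.0


@dataclass
class Ordination:
    """NMDS solution: centered coordinates plus Kruskal stress-1."""

    coordinates: pd.DataFrame  # samples x k, columns NMDS1..NMDSk
    stress: float
    seed: int


def alpha_diversity(counts, sample_id: str = "",
                    bias_corrected: bool = True) -> DiversityProfile:
    """Alpha-diversity profile of a single sample's count vector."""
    counts = np.asarray(counts)
    if counts.ndim != 1 or (counts < 0).any():
        raise ValueError("counts must be a non-negative 1-d vector")
    if counts.sum() == 0:
        raise ValueError("all-zero count vector")
    n = counts.sum()
    f1 = int((counts == 1).sum())
    return DiversityProfile(
        sample_id=sample_id,
        sobs=int((counts > 0).sum()),
        chao1=float(_alpha.chao1(counts, bias_corrected=bias_corrected)),
        ace=float(_alpha.ace(counts, rare_threshold=10)),
        shannon=float(_alpha.shannon(counts, base=2)),
        coverage=float(1.0 - f1 / n),
    )


def alpha_diversity_table(table: OTUTable, **kwargs) -> pd.DataFrame:
    """Alpha diversity for every sample of an OTU table."""
    rows = []
    depths = table.counts.sum(axis=1)
    logger.info("alpha diversity on %d samples, depth %d-%d",
                table.n_samples, depths.min(), depths.max())
    for sid in table.sample_ids:
        p = alpha_diversity(table.counts.loc[sid].to_numpy(), sid, **kwargs)
        rows.append(pd.Series({"sobs": p.sobs, "chao1": p.chao1,
                               "ace": p.ace, "shannon": p.shannon,
                               "coverage": p.coverage}, name=sid))
    out = pd.DataFrame(rows)
    out.index.name = "sample_id"
    return out


def coefficient_of_variation(values) -> float:
    """Sample CV in percent: 100 * sd(n-1) / mean."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


def bray_curtis_matrix(table: OTUTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples, on raw counts."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("zero-total sample")
    d = squareform(pdist(counts, metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


def nmds(dist: DistanceMatrix, k: int = 2, restarts: int = 20,
         seed: int = 0, depths=None) -> Ordination:
    """Non-metric MDS on a precomputed distance matrix.

    Best-stress solution over ``restarts`` seeded initialisations;
    coordinates are centered, NMDS1 sign canonicalised against
    ``depths`` (per-sample read totals) when given, else against the
    first sample's sign, keeping the result deterministic for a seed.
    """
    if k < 1 or restarts < 1:
        raise ValueError("k and restarts must be >= 1")
    d = np.asarray(dist.data, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("non-finite distances")

    def _make(n_init):
        return MDS(n_components=k, metric_mds=False, metric="precomputed",
                   n_init=n_init, random_state=int(seed),
                   normalized_stress=True, max_iter=500)
    # classical (Torgerson) scaling is a strong deterministic start;
    # random restarts guard against its occasional local optima
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:k]
    classical = V[:, order] * np.sqrt(np.clip(w[order], 0, None))
    model = _make(1)
    coords = model.fit_transform(d, init=classical)
    if restarts > 1:
        alt = _make(restarts - 1)
        alt_coords = alt.fit_transform(d)
        if alt.stress_ < model.stress_:
            model, coords = alt, alt_coords
    coords = coords - coords.mean(axis=0)
    if depths is not None:
        ref = rankdata(np.asarray(depths, dtype=float))
    else:
        ref = None
    for j in range(k):
        col = coords[:, j]
        if ref is not None and np.std(ref) > 0:
            r = pearsonr(col, ref)[0]
            flip = np.isfinite(r) and r < 0
        else:
            nz = np.flatnonzero(col)
            flip = len(nz) > 0 and col[nz[0]] < 0
        if flip:
            coords[:, j] = -col
    frame = pd.DataFrame(coords, index=list(dist.ids),
                         columns=[f"NMDS{j + 1}" for j in range(k)])
    frame.index.name = "sample_id"
    return Ordination(coordinates=frame, stress=float(model.stress_),
                      seed=int(seed))
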