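"""RMT-thresholded co-occurrence network construction and analysis.

The pipeline follows the molecular-ecological-network lineage: keep
core OTUs (present in >= 90% of samples), compute Pearson correlations
on log10 relative abundances, pick the correlation cutoff ``St`` by a
random-matrix-theory criterion, build the unweighted-topology graph,
partition it with Clauset-Newman-Moore greedy modularity, compare
against a degree-preserving rewired null ensemble, and classify each
node's topological role from its within-module degree z-score (Zi) and
among-module participation coefficient (Pi).

The RMT criterion: as the threshold rises, the nearest-neighbour
spacing distribution (NNSD) of the unfolded eigenvalues of the
thresholded correlation matrix shifts from the Gaussian-orthogonal-
ensemble (Wigner) form typical of noise-dominated matrices to the
Poisson form typical of modular systems.  ``St`` is the smallest
candidate where the Poisson fit beats the GOE fit and is itself
acceptable, sustained for two consecutive candidates.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_comm
from scipy import stats
from scipy.interpolate import LSQUnivariateSpline
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .association import MantelResult, mantel
from .tables_io import OTUTable

logger = logging.getLogger(__name__)

ZI_THRESHOLD = 2.5    # module-hub cut on within-module degree z-score
PI_THRESHOLD = 0.62   # connector cut on participation coefficient

NNSD_BIN_WIDTH = 0.1
NNSD_RANGE = (0.0, 3.0)
EIGENVALUE_DEDUP_GAP = 1e-8
UNFOLD_KNOTS = 10


@dataclass
class CorrelationMatrix:
    otu_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.otu_ids):
            raise ValueError("correlation matrix shape mismatch")
        if np.abs(v - v.T).max() > 1e-12:
            raise ValueError("correlation matrix not symmetric")
        if np.abs(np.diag(v) - 1.0).max() > 1e-12:
            raise ValueError("correlation matrix diagonal must be 1")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.otu_ids)


@dataclass
class ThresholdScan:
    """Per-candidate NNSD statistics and the selected cutoff ``St``."""

    table: pd.DataFrame  # threshold, n_retained_nodes, chi2_poisson, chi2_goe
    selected_st: float


@dataclass
class NetworkTopology:
    n_nodes: int
    n_links: int
    avg_k: float
    gd: float
    avg_cc: float
    density: float
    power_law_r2: float
    modularity_q: float


@dataclass
class ModuleSet:
    """Partition of network nodes into modules, largest first (M1, M2...)."""

    membership: dict[str, int]  # node -> 1-based module id
    modularity_q: float

    @property
    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for m in self.membership.values():
            out[m] = out.get(m, 0) + 1
        return dict(sorted(out.items()))

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values()))

    def members(self, module_id: int) -> list[str]:
        return [n for n, m in self.membership.items() if m == module_id]

    def dominant(self, k: int = 8) -> list[int]:
        """The k largest modules by node count (ties by module id)."""
        ranked = sorted(self.sizes.items(), key=lambda kv: (-kv[1], kv[0]))
        return [m for m, _ in ranked[:k]]


@dataclass
class NodeRole:
    node: str
    zi: float
    pi: float
    role: str  # peripheral | module_hub | connector | network_hub


@dataclass
class NullStats:
    n_random: int
    metrics: pd.DataFrame  # index metric; columns null_mean, null_sd,
    #                        empirical, z
    replicates: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# construction

def prevalence_filter(table: OTUTable, min_prevalence: float = 0.9
                      ) -> OTUTable:
    """Keep OTUs present (count > 0) in at least a fraction of samples.

    The cut is ``ceil(min_prevalence * n_samples)`` samples.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    need = math.ceil(min_prevalence * table.n_samples)
    presence = (table.counts > 0).sum(axis=0)
    keep = presence.index[presence >= need].tolist()
    if not keep:
        raise ValueError(
            f"no OTU present in >= {need} samples; lower the threshold")
    logger.info("prevalence filter %.0f%%: %d of %d OTUs kept",
                100 * min_prevalence, len(keep), table.n_otus)
    return table.subset_otus(keep)


def correlation_matrix(table: OTUTable, transform: str = "log10_relabund"
                       ) -> CorrelationMatrix:
    """Pairwise Pearson correlation between OTUs across samples.

    Default transform: per-sample relative abundance, zeros filled with
    half the smallest nonzero relative abundance, then log10.
    Zero-variance OTUs are excluded with a warning.
    """
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples")
    if table.n_otus < 2:
        raise ValueError("need at least 2 OTUs")
    rel = table.relative_abundance().to_numpy()
    if transform == "log10_relabund":
        pseudo = rel[rel > 0].min() / 2.0
        x = np.log10(np.where(rel > 0, rel, pseudo))
    elif transform == "none":
        x = rel
    else:
        raise ValueError(f"unknown transform {transform!r}")
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [o for o, k in zip(table.otu_ids, keep) if not k]
        warnings.warn(f"excluding {len(dropped)} zero-variance OTU(s)",
                      stacklevel=2)
    ids = [o for o, k in zip(table.otu_ids, keep) if k]
    r = np.corrcoef(x[:, keep], rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(otu_ids=ids, values=r)


# ---------------------------------------------------------------------------
# RMT threshold

def unfold_spacings(eigenvalues: np.ndarray) -> np.ndarray:
    """Nearest-neighbour spacings of spectrally unfolded eigenvalues.

    Near-duplicate eigenvalues (gap < 1e-8) are dropped, the cumulative
    spectral function is smoothed with a 10-knot cubic spline, and the
    spacings are rescaled to unit mean.
    """
    ev = np.sort(np.asarray(eigenvalues, dtype=float))
    keep = np.concatenate([[True], np.diff(ev) >= EIGENVALUE_DEDUP_GAP])
    ev = ev[keep]
    n = len(ev)
    if n < 12:
        raise ValueError("too few distinct eigenvalues to unfold")
    cumulative = np.arange(1, n + 1, dtype=float)
    qs = np.linspace(0, 1, UNFOLD_KNOTS + 2)[1:-1]
    knots = np.quantile(ev, qs)
    knots = np.unique(knots[(knots > ev[0]) & (knots < ev[-1])])
    try:
        spline = LSQUnivariateSpline(ev, cumulative, knots, k=3)
        unfolded = spline(ev)
    except Exception:  # ill-conditioned knot layout on tiny spectra
        unfolded = np.interp(ev, ev, cumulative)
    spacings = np.diff(np.sort(unfolded))
    spacings = spacings[spacings > 0]
    mean = spacings.mean()
    if mean <= 0:
        raise ValueError("degenerate unfolded spectrum")
    return spacings / mean


def _pooled_chi2(observed: np.ndarray, expected: np.ndarray,
                 min_expected: float = 5.0) -> tuple[float, int]:
    """Pearson chi-square with adjacent bins pooled (Cochran's rule)."""
    obs_p, exp_p = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            obs_p.append(o_acc)
            exp_p.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0 and exp_p:
        obs_p[-1] += o_acc
        exp_p[-1] += e_acc
    elif e_acc > 0:
        obs_p, exp_p = [o_acc], [e_acc]
    obs_p, exp_p = np.asarray(obs_p), np.asarray(exp_p)
    chi2 = float(np.sum((obs_p - exp_p) ** 2 / exp_p))
    return chi2, len(obs_p)


def nnsd_chi2(spacings: np.ndarray) -> tuple[float, float, int]:
    """Chi-square distances of an NNSD to Poisson and GOE predictions.

    Histogram on [0, 3] with bin width 0.1 plus an overflow bin;
    expected counts integrate the Poisson density ``exp(-d)`` and the
    Wigner surmise ``(pi d / 2) exp(-pi d^2 / 4)`` over each bin, and
    adjacent bins are pooled until each expected count reaches 5.
    Returns ``(chi2_poisson, chi2_goe, n_poisson_bins)`` where the bin
    count feeds the chi-square critical value (df = bins - 1).
    """
    spacings = np.asarray(spacings, dtype=float)
    lo, hi = NNSD_RANGE
    edges = np.arange(lo, hi + NNSD_BIN_WIDTH / 2, NNSD_BIN_WIDTH)
    observed, _ = np.histogram(spacings, bins=edges)
    observed = np.append(observed, (spacings >= hi).sum())  # overflow
    n = len(spacings)
    a = np.append(edges[:-1], hi)
    b = np.append(edges[1:], np.inf)
    p_poisson = np.exp(-a) - np.where(np.isinf(b), 0.0, np.exp(-b))
    goe_tail = np.exp(-np.pi * a ** 2 / 4)
    p_goe = goe_tail - np.where(np.isinf(b), 0.0,
                                np.exp(-np.pi * b ** 2 / 4))
    chi2_p, bins_p = _pooled_chi2(observed, n * p_poisson)
    chi2_g, _ = _pooled_chi2(observed, n * p_goe)
    return chi2_p, chi2_g, bins_p


def _thresholded_submatrix(r: np.ndarray, t: float) -> np.ndarray:
    """Zero |r| < t off-diagonal; restrict to rows with a survivor."""
    a = r.copy()
    off = ~np.eye(a.shape[0], dtype=bool)
    a[off & (np.abs(a) < t)] = 0.0
    keep = (np.abs(a) > 0).sum(axis=1) > 1  # diagonal always survives
    return a[np.ix_(keep, keep)]


def rmt_threshold(corr: CorrelationMatrix, t_min: float = 0.3,
                  t_max: float = 0.99, step: float = 0.01) -> ThresholdScan:
    """Scan candidate cutoffs and select ``St`` by the RMT criterion.

    For each candidate the NNSD of the thresholded matrix is compared
    with the Poisson and GOE forms; ``St`` is the smallest candidate
    where the Poisson chi-square beats the GOE chi-square and falls
    below the 0.95 chi-square critical value for the occupied bins,
    sustained for two consecutive candidates.
    """
    if corr.n < 50:
        warnings.warn("fewer than 50 nodes; RMT spectra may be unstable",
                      stacklevel=2)
    candidates = np.round(np.arange(t_min, t_max + step / 2, step), 10)
    rows = []
    flags = []
    for t in candidates:
        sub = _thresholded_submatrix(corr.values, t)
        n_kept = sub.shape[0]
        if n_kept < 10:
            break
        try:
            spacings = unfold_spacings(np.linalg.eigvalsh(sub))
            chi2_p, chi2_g, occupied = nnsd_chi2(spacings)
        except ValueError:
            break
        crit = stats.chi2.ppf(0.95, df=max(occupied - 1, 1))
        ok = chi2_p < chi2_g and chi2_p < crit
        rows.append({"threshold": float(t), "n_retained_nodes": n_kept,
                     "chi2_poisson": chi2_p, "chi2_goe": chi2_g,
                     "poisson_fit_ok": ok})
        flags.append(ok)
    table = pd.DataFrame(rows)
    selected = None
    for i in range(len(flags) - 1):
        if flags[i] and flags[i + 1]:
            selected = float(table.loc[i, "threshold"])
            break
    if selected is None:
        raise ValueError("no RMT transition in scan range")
    logger.info("RMT scan selected St = %.2f", selected)
    return ThresholdScan(table=table, selected_st=selected)


# ---------------------------------------------------------------------------
# graph construction and topology

def build_network(corr: CorrelationMatrix, st: float) -> nx.Graph:
    """Threshold the correlation matrix into an undirected graph.

    Edge (i, j) iff ``|r_ij| >= st``; attributes ``weight = |r|`` and
    ``sign``; isolated nodes are dropped.
    """
    if not 0 < st < 1:
        raise ValueError("st must be in (0, 1)")
    g = nx.Graph()
    r = corr.values
    ii, jj = np.where(np.triu(np.abs(r) >= st, k=1))
    if len(ii) == 0:
        raise ValueError(f"no edge survives |r| >= {st}")
    for i, j in zip(ii, jj):
        g.add_edge(corr.otu_ids[i], corr.otu_ids[j],
                   weight=float(abs(r[i, j])),
                   sign=1 if r[i, j] > 0 else -1)
    return g


def _power_law_r2(g: nx.Graph) -> float:
    degrees = np.array([d for _, d in g.degree()])
    ks, freq = np.unique(degrees[degrees > 0], return_counts=True)
    if len(ks) < 2:
        return 1.0
    fit = np.polyfit(np.log10(ks), np.log10(freq), 1)
    pred = np.polyval(fit, np.log10(ks))
    resid = np.log10(freq) - pred
    ss_tot = float(((np.log10(freq) - np.log10(freq).mean()) ** 2).sum())
    return 1.0 if ss_tot == 0 else float(1.0 - (resid ** 2).sum() / ss_tot)


def average_geodesic_distance(g: nx.Graph) -> float:
    """Mean shortest-path length over reachable ordered pairs.

    Disconnected graphs average within components.
    """
    total, pairs = 0, 0
    for node, lengths in nx.all_pairs_shortest_path_length(g):
        for other, d in lengths.items():
            if other != node:
                total += d
                pairs += 1
    return total / pairs if pairs else float("nan")


def network_topology(g: nx.Graph,
                     modules: "ModuleSet | None" = None) -> NetworkTopology:
    """Standard topological summary of a co-occurrence network."""
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n < 3:
        raise ValueError("need at least 3 nodes")
    if modules is None:
        modules = detect_modules(g)
    return NetworkTopology(
        n_nodes=n, n_links=e,
        avg_k=2.0 * e / n,
        gd=average_geodesic_distance(g),
        avg_cc=float(nx.average_clustering(g)),  # degree<2 contributes 0
        density=2.0 * e / (n * (n - 1)),
        power_law_r2=_power_law_r2(g),
        modularity_q=modules.modularity_q,
    )


def detect_modules(g: nx.Graph) -> ModuleSet:
    """Clauset-Newman-Moore greedy modularity partition (unweighted).

    Modules are numbered 1..M by decreasing size (ties by smallest
    member under lexical order), making the labelling deterministic.
    """
    communities = nx_comm.greedy_modularity_communities(g, weight=None)
    q = nx_comm.modularity(g, communities, weight=None)
    ordered = sorted((sorted(c) for c in communities),
                     key=lambda c: (-len(c), c[0]))
    membership = {node: mid for mid, nodes in enumerate(ordered, start=1)
                  for node in nodes}
    return ModuleSet(membership=membership, modularity_q=float(q))


# ---------------------------------------------------------------------------
# null model and roles

def rewire_degree_preserving(g: nx.Graph, rng: np.random.Generator,
                             swaps_per_edge: int = 10) -> nx.Graph:
    """Degree-preserving randomisation by attempted double-edge swaps.

    ``swaps_per_edge * E`` swap attempts; candidates creating self-loops
    or multi-edges are rejected, so every replicate keeps the exact
    degree sequence.
    """
    edges = [tuple(e) for e in g.edges()]
    e = len(edges)
    if e < 2:
        raise ValueError("need at least 2 edges to rewire")
    degrees = dict(g.degree())
    if max(degrees.values()) >= g.number_of_nodes() - 1 and e > 2:
        pass  # swaps may often reject, but remain well-defined
    edge_set = set(frozenset(x) for x in edges)
    attempts = swaps_per_edge * e
    idx = rng.integers(0, e, size=(attempts, 2))
    coin = rng.integers(0, 2, size=attempts)
    for (i, j), c in zip(idx, coin):
        if i == j:
            continue
        a, b = edges[i]
        u, v = edges[j]
        if c:
            u, v = v, u
        # propose (a, u) and (b, v)
        if a == u or b == v:
            continue
        new1, new2 = frozenset((a, u)), frozenset((b, v))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((u, v)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = (a, u)
        edges[j] = (b, v)
    out = nx.Graph()
    out.add_nodes_from(g.nodes())
    out.add_edges_from(edges)
    return out


def _fast_metrics(g: nx.Graph) -> dict[str, float]:
    """GD, avgCC and greedy-modularity Q via igraph (C implementation
    of the same Clauset-Newman-Moore agglomeration); used inside the
    null ensemble where only ensemble moments matter."""
    import igraph as ig

    nodes = list(g.nodes())
    idx = {n: i for i, n in enumerate(nodes)}
    h = ig.Graph(n=len(nodes),
                 edges=[(idx[u], idx[v]) for u, v in g.edges()])
    return {
        "gd": h.average_path_length(unconn=True),
        "avg_cc": h.transitivity_avglocal_undirected(mode="zero"),
        "modularity": h.community_fastgreedy().as_clustering().modularity,
    }


def null_model_ensemble(g: nx.Graph, n_random: int = 100,
                        seed: int = 0) -> NullStats:
    """Degree-preserving null ensemble with per-replicate GD, avgCC, Q.

    Returns null mean +- sd (n-1 denominator) per metric and the
    z-score of the empirical network against the ensemble.
    """
    if g.number_of_edges() < 2:
        raise ValueError("need at least 2 edges")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_random):
        r = rewire_degree_preserving(g, rng)
        rows.append(_fast_metrics(r))
    reps = pd.DataFrame(rows)
    empirical = {
        "gd": average_geodesic_distance(g),
        "avg_cc": float(nx.average_clustering(g)),
        "modularity": detect_modules(g).modularity_q,
    }
    metrics = pd.DataFrame({
        "null_mean": reps.mean(),
        "null_sd": reps.std(ddof=1),
        "empirical": pd.Series(empirical),
    })
    metrics["z"] = ((metrics["empirical"] - metrics["null_mean"])
                    / metrics["null_sd"].replace(0, np.nan))
    metrics.index.name = "metric"
    return NullStats(n_random=n_random, metrics=metrics, replicates=reps)


def node_roles(g: nx.Graph, modules: ModuleSet) -> list[NodeRole]:
    """Zi-Pi classification of every node's topological role.

    Zi is the z-score of a node's within-module degree among its module
    mates (0 when the module's spread is zero); Pi is the participation
    coefficient ``1 - sum_s (k_is / k_i)^2``.  Cutoffs 2.5 / 0.62 give
    peripherals, module hubs, connectors and network hubs.
    """
    member = modules.membership
    if set(member) != set(g.nodes()):
        raise ValueError("module partition does not cover the network")
    within = {node: sum(1 for nb in g.neighbors(node)
                        if member[nb] == member[node])
              for node in g.nodes()}
    by_module: dict[int, list[int]] = {}
    for node, k in within.items():
        by_module.setdefault(member[node], []).append(k)
    mod_stats = {m: (np.mean(ks), np.std(ks)) for m, ks in by_module.items()}
    roles = []
    for node in g.nodes():
        mean, sd = mod_stats[member[node]]
        zi = 0.0 if sd == 0 else (within[node] - mean) / sd
        k = g.degree(node)
        split: dict[int, int] = {}
        for nb in g.neighbors(node):
            split[member[nb]] = split.get(member[nb], 0) + 1
        pi = 1.0 - sum((ks / k) ** 2 for ks in split.values())
        if zi >= ZI_THRESHOLD and pi >= PI_THRESHOLD:
            role = "network_hub"
        elif zi >= ZI_THRESHOLD:
            role = "module_hub"
        elif pi >= PI_THRESHOLD:
            role = "connector"
        else:
            role = "peripheral"
        roles.append(NodeRole(node=node, zi=float(zi), pi=float(pi),
                              role=role))
    return roles


# ---------------------------------------------------------------------------
# module-environment association and export

def module_environment_mantel(table: OTUTable, modules: ModuleSet,
                              env: pd.DataFrame, permutations: int = 999,
                              seed: int = 0, min_module_size: int = 5,
                              module_ids=None) -> pd.DataFrame:
    """Mantel test of each module's community distance vs each variable.

    Per module: Bray-Curtis between samples restricted to member OTUs;
    per environmental variable: Euclidean distance on the z-scored
    values.  Spearman Mantel, one-tailed.  Modules smaller than
    ``min_module_size`` OTUs are skipped with a warning.
    """
    env = env.loc[table.sample_ids]
    records = []
    ids = module_ids if module_ids is not None else sorted(modules.sizes)
    for mid in ids:
        members = [o for o in modules.members(mid) if o in table.otu_ids]
        if len(members) < min_module_size:
            warnings.warn(f"module {mid} has {len(members)} OTUs; skipped",
                          stacklevel=2)
            continue
        sub = table.counts[members].to_numpy(dtype=float)
        ok = sub.sum(axis=1) > 0
        labels = [s for s, keep in zip(table.sample_ids, ok) if keep]
        d_comm = DistanceMatrix(
            squareform(pdist(sub[ok], metric="braycurtis")), ids=labels)
        for var in env.columns:
            v = env.loc[labels, var].to_numpy(dtype=float)
            z = (v - v.mean()) / v.std() if v.std() > 0 else v * 0.0
            d_env = DistanceMatrix(
                squareform(pdist(z[:, None], metric="euclidean")), ids=labels)
            res: MantelResult = mantel(d_comm, d_env, method="spearman",
                                       permutations=permutations, seed=seed)
            records.append({"module": mid, "variable": var, "r": res.r,
                            "p": res.p_value,
                            "permutations": res.permutations})
    return pd.DataFrame(records)


def export_network(g: nx.Graph, modules: ModuleSet, roles: list[NodeRole],
                   path, fmt: str = "gexf",
                   taxonomy: dict[str, str] | None = None) -> None:
    """Write the annotated network for external visualisation tools.

    Node attributes: module, zi, pi, role, phylum; edge attributes:
    weight, sign.  Formats: gexf, graphml, edgelist_tsv.
    """
    role_of = {r.node: r for r in roles}
    out = g.copy()
    for node in out.nodes():
        r = role_of[node]
        lineage = (taxonomy or {}).get(node, "Unclassified")
        phylum = lineage.split(";")[1].strip() if ";" in lineage else lineage
        out.nodes[node].update(module=modules.membership[node],
                               zi=r.zi, pi=r.pi, role=r.role, phylum=phylum)
    if fmt == "gexf":
        nx.write_gexf(out, path)
    elif fmt == "graphml":
        nx.write_graphml(out, path)
    elif fmt == "edgelist_tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tweight\tsign\n")
            for u, v, d in out.edges(data=True):
                fh.write(f"{u}\t{v}\t{d['weight']:.6g}\t{d['sign']}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
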