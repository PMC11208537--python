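"""Synthetic paddy-soil microbiome datasets with known ground truth.

The generator emulates the downstream product of a 16S amplicon survey
of Cd/Pb-polluted paddy fields: ~45 samples at 110k-128k reads each,
thousands of OTUs, a pH-like latent gradient driving part of the
community, correlated heavy-metal covariates, and planted co-occurring
OTU modules — so that every pipeline stage (diversity, regressions,
Mantel tests, RMT network construction, module detection, Zi-Pi roles)
has a recoverable truth.

Generative model, per sample ``j`` and OTU ``i``::

    g_j  ~ Normal(5.4, 0.3) truncated to [4.5, 6.5]      (pH-like)
    z_j  = (g_j - 5.4) / 0.3                              (standardised)
    u_mj ~ Normal(0, 1)          shared within planted module m
    log-intensity_ij = baseline_i + beta_i z_j + lambda_i u_m(i)j + eps_ij
    counts_j ~ Multinomial(depth_j, softmax(log-intensity_j))

Soil covariates (CEC, TN, AP, AK, SOM) are increasing linear functions
of ``g_j`` plus noise; total metals are log-normal with Cd mildly tied
to acidity, and DTPA fractions Beta-distributed below the totals.
The multinomial-softmax step makes counts compositional, as real
amplicon data is.  Everything is deterministic given the seed.

This module also packages the printed soil/metal fixture tables and
their regional background values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import (BackgroundTable, MetalTable, OTUTable,
                        SoilProfileTable, read_background_table,
                        read_metal_table, read_soil_table)

PSEUDO_PHYLA = [
    "Proteobacteria_like", "Acidobacteria_like", "Chloroflexi_like",
    "Planctomycetes_like", "Actinobacteria_like", "Gemmatimonadetes_like",
    "Patescibacteria_like", "Verrucomicrobia_like", "Bacteroidetes_like",
    "Nitrospirae_like",
]
# heavy-tailed phylum weights mirroring a dominant-phylum community
PHYLUM_WEIGHTS = np.array([0.30, 0.20, 0.10, 0.08, 0.07, 0.06,
                           0.06, 0.05, 0.04, 0.04])


@dataclass
class GeneratorParams:
    """Knobs of the synthetic community; defaults match the surveyed
    study conditions (45 fields, ~2000 taxa, 8 planted modules,
    110k-128k reads per sample)."""

    n_samples: int = 45
    n_taxa: int = 2000
    n_modules: int = 8
    module_size_range: tuple[int, int] = (20, 100)
    gradient_effect_scale: float = 1.0
    module_loading: float = 1.2
    diffuse_effect_sd: float = 0.8  # gradient response of unplanted OTUs
    noise_sd: float = 0.5
    depth_range: tuple[int, int] = (110_000, 128_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_taxa, self.n_modules) <= 0:
            raise ValueError("sizes must be positive")
        lo, hi = self.module_size_range
        if not 0 < lo <= hi:
            raise ValueError("bad module size range")
        if self.n_modules * hi > self.n_taxa:
            raise ValueError("module sizes infeasible for n_taxa")
        if self.noise_sd <= 0 or self.module_loading < 0:
            raise ValueError("bad loading/noise parameters")


@dataclass
class SyntheticBundle:
    otu: OTUTable
    soil: SoilProfileTable
    metals: MetalTable
    truth: dict = field(repr=False, default_factory=dict)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _soil_from_gradient(rng: np.random.Generator, g: np.ndarray,
                        sample_ids: list[str]) -> SoilProfileTable:
    n = len(g)
    dg = g - 5.4
    clay = np.clip(22 + 2.5 * dg + rng.normal(0, 1.5, n), 12, 35)
    silt = np.clip(32 + 1.0 * dg + rng.normal(0, 1.0, n), 25, 40)
    sand = 100.0 - clay - silt
    df = pd.DataFrame({
        "som": np.clip(36.5 + 8 * dg + rng.normal(0, 4, n), 5, None),
        "ph": g,
        "cec": np.clip(8.8 + 4 * dg + rng.normal(0, 1.2, n), 1, None),
        "ec": np.clip(120 + rng.normal(0, 30, n), 20, None),
        "clay": clay, "silt": silt, "sand": sand,
        "tn": np.clip(1.96 + 0.8 * dg + rng.normal(0, 0.3, n), 0.2, None),
        "an": np.clip(140 + 30 * dg + rng.normal(0, 15, n), 40, None),
        "ap": np.clip(95 + 50 * dg + rng.normal(0, 20, n), 5, None),
        "ak": np.clip(90 + 20 * dg + rng.normal(0, 10, n), 30, None),
    }, index=pd.Index(sample_ids, name="sample_id"))
    return SoilProfileTable(df)


def _metals_from_gradient(rng: np.random.Generator, g: np.ndarray,
                          sample_ids: list[str]) -> MetalTable:
    n = len(g)
    total = pd.DataFrame({
        "Cd": np.exp(np.log(0.8) + 0.3 * (5.4 - g) + rng.normal(0, 0.8, n)),
        "Cu": np.exp(np.log(13.0) + rng.normal(0, 0.3, n)),
        "Pb": np.exp(np.log(39.0) + rng.normal(0, 0.25, n)),
        "Zn": np.exp(np.log(57.0) + rng.normal(0, 0.3, n)),
    }, index=pd.Index(sample_ids, name="sample_id"))
    frac = rng.beta(4, 4, size=total.shape)
    dtpa = total * frac
    return MetalTable(total=total, dtpa=dtpa)


def generate_dataset(params: GeneratorParams | None = None,
                     **overrides) -> SyntheticBundle:
    """Draw one synthetic bundle (OTU + soil + metal tables + truth).

    ``truth`` carries ``module_of`` (otu -> planted module id or None),
    ``gradient`` (per-sample latent value), ``effect`` (per-OTU
    gradient coefficient) and ``hub_otus`` (the highest-loading member
    of each planted module).
    """
    if params is None:
        params = GeneratorParams(**overrides)
    elif overrides:
        raise TypeError("pass either params or keyword overrides, not both")
    rng = np.random.default_rng(params.seed)
    n, m = params.n_samples, params.n_taxa
    sample_ids = [f"S{j + 1:03d}" for j in range(n)]
    otu_ids = [f"OTU_{i + 1}" for i in range(m)]

    g = _truncated_normal(rng, 5.4, 0.3, 4.5, 6.5, n)
    z = (g - 5.4) / 0.3
    soil = _soil_from_gradient(rng, g, sample_ids)
    metals = _metals_from_gradient(rng, g, sample_ids)

    # planted modules occupy the first sum(sizes) OTUs
    lo, hi = params.module_size_range
    sizes = rng.integers(lo, hi + 1, size=params.n_modules)
    module_of: dict[str, int | None] = {o: None for o in otu_ids}
    loading = np.zeros(m)
    baseline = rng.normal(0.0, 1.5, m)
    # 30% of unplanted OTUs respond diffusely to the gradient, making it
    # the dominant community-wide axis (a pH-driven community) while the
    # module factors stay local
    beta = np.where(rng.random(m) < 0.7, 0.0,
                    rng.normal(0, params.diffuse_effect_sd, m))
    hub_otus: list[str] = []
    start = 0
    for mod in range(params.n_modules):
        members = np.arange(start, start + sizes[mod])
        start += sizes[mod]
        for i in members:
            module_of[otu_ids[i]] = mod + 1
        lam = params.module_loading * rng.uniform(0.7, 0.95, len(members))
        lam[0] = params.module_loading  # the planted hub
        loading[members] = lam
        hub_otus.append(otu_ids[members[0]])
        baseline[members] = rng.normal(1.0, 0.7, len(members))
        # modules 1 / 2 respond to the gradient (+/-); the rest do not
        gamma = {1: params.gradient_effect_scale,
                 2: -params.gradient_effect_scale}.get(mod + 1, 0.0)
        beta[members] = gamma + rng.normal(0, 0.05, len(members))

    u = rng.normal(0, 1, size=(params.n_modules, n))
    eps = rng.normal(0, params.noise_sd, size=(n, m))
    intensity = baseline[None, :] + np.outer(z, beta) + eps
    for mod in range(params.n_modules):
        idx = [i for i, o in enumerate(otu_ids)
               if module_of[o] == mod + 1]
        intensity[:, idx] += np.outer(u[mod], loading[idx])

    probs = np.exp(intensity - intensity.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    depths = rng.integers(params.depth_range[0], params.depth_range[1] + 1,
                          size=n)
    counts = np.vstack([rng.multinomial(depths[j], probs[j])
                        for j in range(n)])

    phylum_idx = rng.choice(len(PSEUDO_PHYLA), size=m,
                            p=PHYLUM_WEIGHTS / PHYLUM_WEIGHTS.sum())
    taxonomy = {}
    for i, o in enumerate(otu_ids):
        mod = module_of[o]
        if mod is not None:  # planted modules carry a pseudo-phylum label
            phylum = PSEUDO_PHYLA[(mod - 1) % len(PSEUDO_PHYLA)]
        else:
            phylum = PSEUDO_PHYLA[phylum_idx[i]]
        taxonomy[o] = f"Bacteria;{phylum};Unclassified"

    otu = OTUTable(
        counts=pd.DataFrame(counts,
                            index=pd.Index(sample_ids, name="sample_id"),
                            columns=pd.Index(otu_ids, name="otu_id")),
        taxonomy=taxonomy)
    truth = {"module_of": module_of,
             "gradient": dict(zip(sample_ids, g.tolist())),
             "effect": dict(zip(otu_ids, beta.tolist())),
             "hub_otus": hub_otus,
             "params": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in vars(params).items()}}
    return SyntheticBundle(otu=otu, soil=soil, metals=metals, truth=truth)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.otu.write(outdir / "otu.tsv")
    bundle.soil.write(outdir / "soil.tsv")
    bundle.metals.write(outdir / "metals.tsv")
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.truth, fh, indent=1)


def _fixture_path(name: str):
    return resources.files("paddynet").joinpath("data", name)


def paper_fixture() -> tuple[SoilProfileTable, MetalTable, BackgroundTable]:
    """The packaged 15-site soil and metal tables plus backgrounds.

    Backgrounds: Cd 0.11 and Pb 20.78 mg/kg are the reported Taihu
    regional values; Cu 22.3 and Zn 62.6 mg/kg are synthetic constants
    back-solved so the four-metal PLI reproduces the printed values on
    the rows that reconcile.
    """
    with resources.as_file(_fixture_path("table1.tsv")) as p:
        soil = read_soil_table(p)
    with resources.as_file(_fixture_path("table2.tsv")) as p:
        metals = read_metal_table(p)
    with resources.as_file(_fixture_path("backgrounds.tsv")) as p:
        backgrounds = read_background_table(p)
    return soil, metals, backgrounds


def fixture_printed_pli() -> pd.Series:
    """The printed PLI column of the packaged metal table."""
    with resources.as_file(_fixture_path("table2.tsv")) as p:
        df = pd.read_csv(p, sep="\t").set_index("sample_id")
    return df["PLI"]
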