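# paddynet

Tools for analysing soil-microbiome surveys of heavy-metal-polluted
paddy fields: pollution indices on measured metal concentrations,
bacterial alpha/beta diversity, environment–community association
statistics, and random-matrix-theory (RMT)-thresholded co-occurrence
networks with module and keystone-role analysis. A synthetic-data
generator with planted ground truth makes every stage testable without
any sequencing download.

## The problem

Paddy soils near industrial areas accumulate Cd and Pb. Such surveys
ask three questions: *how polluted is each field*, *which soil
variables drive the bacterial community*, and *how are taxa organised
into co-occurring modules, and which taxa are keystones*. The package
implements the standard quantitative toolbox for each:

**Pollution.** Per metal, the contamination factor is the ratio to the
regional background, CF = C / C_background; the pollution load index
aggregates the assessed metals as the geometric mean
PLI = (CF₁ × … × CFₙ)^(1/n), with PLI > 1 indicating pollution. A
pH-dependent Cd risk screen applies the GB 15618-2018 thresholds for
paddy soil (0.3 mg/kg at pH ≤ 5.5, 0.4 mg/kg at 5.5 < pH ≤ 6.5).

**Diversity.** Observed richness (Sobs), Chao1 (bias-corrected), ACE
(rare cutoff 10), Shannon in bits and Good's coverage per sample;
Bray–Curtis dissimilarity between samples; non-metric MDS with Kruskal
stress-1 for the β-diversity axis.

**Association.** Polynomial regressions of diversity on soil
variables; Spearman taxon × environment grids with Benjamini–Hochberg
adjustment; one-tailed Mantel and partial Mantel permutation tests
between distance matrices; variation partitioning (partial RDA on
Hellinger-transformed abundances, Ezekiel-adjusted R²); random-forest
%IncMSE predictor importance.

**Networks.** Core OTUs (present in ≥ 90 % of samples) are correlated
pairwise (Pearson, on log10 relative abundance); the cutoff *St* is
selected where the nearest-neighbour spacing distribution of the
unfolded eigenvalues of the thresholded matrix turns from the
Gaussian-orthogonal-ensemble (Wigner) form to the Poisson form; the
thresholded graph is partitioned by Clauset–Newman–Moore greedy
modularity, compared against a degree-preserving rewired null
ensemble, and every node is classified by its within-module degree
z-score (Zi) and participation coefficient (Pi) into peripherals,
module hubs (Zi ≥ 2.5), connectors (Pi ≥ 0.62) and network hubs.

## Worked example

The packaged fixture tables carry a 15-site survey (soil properties,
total and DTPA-extractable Cd/Cu/Pb/Zn) with regional backgrounds
Cd 0.11 and Pb 20.78 mg/kg:

```python
from paddynet import paper_fixture, assess_site

soil, metals, backgrounds = paper_fixture()
res = assess_site(metals.row("YX_1"), backgrounds,
                  ph=float(soil.data.loc["YX_1", "ph"]))
print({m: round(v, 3) for m, v in res.cf.items()})
print(round(res.pli, 3), res.polluted, res.cd_exceeds_screen)
```

prints

```
{'Cd': 14.727, 'Cu': 0.383, 'Pb': 1.723, 'Zn': 0.537}
1.511 True True
```

— site YX_1 carries 14.7× the background Cd, its four-metal PLI of
1.51 marks it polluted, and its total Cd exceeds the pH-dependent risk
screening value. From the shell, the same assessment over all sites:

```sh
paddynet pollution --metals table2.tsv --soil table1.tsv \
    --backgrounds bg.tsv --out pollution.tsv
# -> wrote pollution.tsv (15/15 sites polluted)
```

A full network run on a synthetic community with eight planted modules
at strong within-module loading:

```python
from paddynet import generate_dataset, GeneratorParams, network

b = generate_dataset(GeneratorParams(seed=7, module_loading=1.5,
                                     noise_sd=0.3))
core = network.prevalence_filter(b.otu, 0.9)
corr = network.correlation_matrix(core)
scan = network.rmt_threshold(corr)
g = network.build_network(corr, scan.selected_st)
mods = network.detect_modules(g)
print(scan.selected_st, g.number_of_nodes(), g.number_of_edges(),
      round(mods.modularity_q, 3))
```

prints `0.73 1116 23797 0.715`: the RMT scan picks the cutoff 0.73,
and the greedy partition of the resulting 1116-node graph recovers the
planted modules exactly (adjusted Rand index 1.0 against the
generator's truth; see `tests/test_acceptance.py`).

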