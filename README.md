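# metapatch

Network-based analysis of waterbird metacommunity dynamics across
hydrological regimes.

Wintering waterbirds in large river-connected lake systems redistribute
themselves every year as the water recedes: an early recession, a late
recession, a normal one, or an extreme drought each exposes a different
mix of open water, mudflat and sedge meadow, in the river-connected
sub-lakes but not in the stable lakes that surround them. `metapatch` is
for ecologists who ask how such a metacommunity reorganizes: it treats
each winter's survey as a bipartite **species–patch network** (species
and habitat patches as nodes, occurrence as a link) and quantifies the
rewiring between winters.

## The statistics at its core

For two period networks with link sets L1, L2, let a = |L1 ∩ L2|,
b = |L1 \ L2|, c = |L2 \ L1|. The temporal beta diversity of links is
the Jaccard dissimilarity

    β_T = (b + c) / (a + b + c)

with two exact partitions computed from the same tally:

    β_T = β_Extinction + β_Colonization        (lost vs gained links)
    β_T = β_Local + β_Regional + β_Landscape + β_RL

where each changed link is classified by whether its species node and
patch node persist (hold a link at both times): both persist → local
rewiring; species turnover → regional; patch turnover → landscape;
neither → RL.

Per-period network structure is summarized by connectance, NODF
nestedness and Barber bipartite modularity Q_B; per-node structure by
degree (patch richness / species niche width), the node's nestedness
contribution **cnodf** (a z-score against randomizations of the focal
node's links) and the coefficient of variation of both across periods,
compared between species and patches with a Mann–Whitney U test.
Classic community indices (Shannon–Wiener H′, Pielou J′, Bray–Curtis)
and hydrological covariates (inundation duration and its InD1/InD2
classes, regime labelling from October water levels, shoreline shape
index, NDVI) round out the toolkit. A seeded synthetic-scenario
generator emulates the four-regime study design so the whole pipeline is
testable end to end; see `docs/methods.md` for the model and its
assumptions.

## Worked example

Generate a synthetic four-winter survey and partition its dynamics:

```sh
metapatch simulate --seed 11 --out demo/
metapatch beta    --survey demo/survey.tsv --out demo/beta.tsv
metapatch network --survey demo/survey.tsv --out demo/net.tsv
```

`demo/beta.tsv` (rounded):

```
  pair  beta_temporal  beta_extinction  beta_colonization  beta_local  beta_regional  beta_landscape  beta_rl
ER->ED          0.190            0.050              0.140       0.142              0           0.048        0
ER->LR          0.179            0.158              0.021       0.172              0           0.008        0
ER->NR          0.079            0.044              0.035       0.079              0           0.000        0
LR->ED          0.307            0.048              0.259       0.216              0           0.091        0
LR->NR          0.149            0.010              0.139       0.143              0           0.006        0
NR->ED          0.205            0.053              0.152       0.157              0           0.048        0
```

Reading the NR->ED row: about 21% of all species–patch links changed
between the normal-recession and drought winters, and the change is
colonization-dominated (0.152 vs 0.053) — birds spread into patches
(mostly the stable surrounding lakes) they did not use before the
drought. The ER->LR row shows the opposite regime contrast: turnover
into the late-recession winter is extinction-dominated (0.158 vs
0.021), links vanishing as the still-flooded marshes offer no mudflat
or meadow. Most changed links sit in the local component: the species
and patches persist regionally while their pairing rewires.

`demo/net.tsv`:

```
period  n_species  n_patches  n_links  connectance   nodf  modularity_q  n_modules
    ED         40         20      555        0.694 73.894         0.172          3
    ER         40         17      502        0.738 79.593         0.099          2
    LR         40         15      432        0.720 74.446         0.080          3
    NR         40         17      497        0.731 76.121         0.089          3
```

Network-level structure varies only mildly between regimes (high
connectance and nestedness, weak modularity) even while one link in
three rewires — the hallmark the link-level beta partition is designed
to expose. The full pipeline (`metapatch run --config config.yaml`)
additionally writes diversity profiles, per-node degree/cnodf series
with CVs, the species-vs-patch CV comparison and a keystone-patch
ranking, all as deterministic TSV tables plus a manifest.

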