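# endopersist

Seasonal community-assembly and persistency analysis for endophyte (and
other microbiome) count tables.

Plant-associated microbial communities turn over with the seasons, yet
some members and some pairwise associations persist through the whole
year. `endopersist` implements the analysis chain used to characterise
that persistence in multi-season amplicon surveys — for example a
design sampling two sites (a control and a radiation-stressed one), two
tissue types (aerial vs root), four seasons and five plant replicates.
It takes a taxa × samples count table plus sample metadata and answers:

* **How diverse is each community?** Hill numbers of order *q* = 0, 1, 2
  (richness, exponential Shannon entropy, inverse Simpson
  concentration) with sample-size-based rarefaction and extrapolation
  on incidence data.
* **Do season, site or tissue shape composition?** Bray–Curtis
  dissimilarities, NMDS ordination (Kruskal stress-1), one-factor
  PERMANOVA (pseudo-*F*, *R*²) and ANOSIM (*R*), each with seeded
  permutation *p*-values.
* **Is assembly stochastic or deterministic?** Two complementary
  views:
  * the **Sloan neutral community model**, which predicts a taxon's
    occupancy from its mean relative abundance *p* as
    `freq_hat(p) = 1 − B(d; Nm·p, Nm·(1−p))` with *B* the regularized
    incomplete beta CDF, *d* = 1/depth the detection limit and *Nm*
    the migration parameter fitted by nonlinear least squares; taxa
    outside a 95% binomial (Wilson) band around the prediction are
    labelled *above* (selection candidates) or *below* (dispersal
    limitation candidates), and taxa deviating the same way in all
    four seasons are the persistently non-neutral members;
  * the **Raup–Crick index**, a presence/absence null model scoring
    each sample pair in [−1, 1]; pairs with |RCI| < 0.95 share no more
    and no fewer taxa than chance predicts, and their fraction is the
    community-level stochasticity summary.
* **Which associations persist?** Per-season Spearman co-occurrence
  networks (|ρ| > 0.8, *p* < 0.01), combined into a persistence
  network of edges present in ≥ 2 seasons, summarised by node/edge
  counts, edge density `E/(V(V−1))`, transitivity, diameter and
  Freeman centralizations, and compared across panels by Jaccard
  distance on edge sets.

A first-class synthetic-data module generates the full 2×2×4×5 study
with a Dirichlet-multinomial neutral backbone and planted ground truth
(selected/limited taxa, season-persistent correlated pairs), so every
stage is testable end-to-end without any sequencing data.

## Worked example

```python
import endopersist as ep
from endopersist import data_model as dm

# generate the default synthetic study and analyse one group
design = ep.default_design(seed=7)
tables, manifest = ep.generate_study(design)

fits = {}
for season in design.seasons:
    sl = tables[("control", "aerial", season)].drop_empty_taxa()
    fits[season] = ep.fit_ncm(dm.taxon_stats(sl), design.depth, n_boot=0)

print(f"spring Nm = {fits['spring'].Nm:.0f}, r2 = {fits['spring'].r2:.2f}")
records = ep.persistence_across_seasons(fits, min_count=4)
persistent = {r.taxon_id for r in records if r.direction == "above" and r.persistent}
planted = set(manifest["selected_taxa"])
print(f"{len(planted & persistent)}/{len(planted)} planted taxa among the "
      f"{len(persistent)} above prediction in all 4 seasons")
```

prints

```
spring Nm = 1038, r2 = 0.54
8/8 planted taxa among the 51 above prediction in all 4 seasons
```

The fitted *Nm* sits above the generating value (500) and the fit
quality is moderate because the planted non-neutral taxa distort the
occupancy–abundance relationship. All eight taxa planted as
host-selected are above the neutral band in every season; they sit
inside a larger group of persistently-above taxa, because with five
replicates per season any abundant taxon saturates occupancy at 1
while its predicted occupancy stays slightly below — rare taxa with
full occupancy (like the planted ones) are the informative signal.

The command line mirrors the library:

```sh
endopersist simulate --seed 7 --outdir study/       # counts, metadata, truth manifest
endopersist all --seed 7 --outdir results/          # every analysis section
```

`endopersist all` writes per-stage TSV/JSON outputs plus a
`summary.json` indexing them; re-running with the same seed and config
is bit-identical.

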