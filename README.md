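# coalternet

Construction and topological analysis of **morphometric coalteration
("coatrophy") networks** from coordinate-based voxel-based-morphometry
(VBM) meta-analysis data.

Gray-matter alterations in brain disorders do not occur randomly: certain
areas tend to be altered *together* across patient studies. Given only the
peak coordinates ("foci") that VBM studies report, this package asks which
atlas-labeled loci co-occur in their alteration more often than chance, and
what graph these co-alterations form — its hubs, its bridges, and its
densely interconnected core.

The pipeline:

1. **ALE mapping.** Each experiment's foci are smoothed with an isotropic
   3-D Gaussian, p(d) = (σ³(2π)^{3/2})⁻¹ e^{−d²/2σ²} with
   σ = FWHM/√(8 ln 2), into a modeled-alteration (MA) map; MA maps unite
   across experiments as ALE = 1 − ∏ᵢ(1 − MAᵢ) and are thresholded against
   a Monte-Carlo null of randomly placed foci (voxel-level FWE, α = 0.05).
2. **Node construction.** Atlas regions with ≥ 20 suprathreshold voxels
   count as altered; local ALE maxima above the 90th percentile of the
   suprathreshold value distribution, at least 10 mm apart, become
   atlas-labeled network nodes (numbered rostrocaudally within a region).
3. **Coalteration statistics.** A binary experiments × nodes matrix marks
   which experiments altered which nodes. For each node pair, the four
   joint-state probabilities θ₁…θ₄ feed **Patel's κ**:

       E        = (θ₁+θ₂)(θ₁+θ₃)
       max(θ₁)  = min(θ₁+θ₂, θ₁+θ₃)
       min(θ₁)  = max(0, 2θ₁+θ₂+θ₃−1)
       κ        = (θ₁−E) / (D·(max(θ₁)−E) + (1−D)·(E−min(θ₁))),  D = 1{θ₁≥E}

   κ ∈ [−1, 1]; significance is assessed by sampling θ from the flat-prior
   Dirichlet posterior of the 2×2 multinomial and requiring
   P(κ > 0 | data) ≥ 0.99.
4. **Topology.** Node degree (pathoconnectivity hubs), edge betweenness,
   k-core decomposition (the maximal core is the "core subnetwork"),
   interhemispheric vs intrahemispheric edge counts, and a region-merged
   view.

A fully synthetic data generator (toy atlas + coupled-multinomial foci
model with known population κ per pair) makes every stage testable without
any proprietary database.

## Worked example

`examples/01_simulate_and_run.py` simulates 60 experiments over a 10-region
toy atlas with 4 truly coupled region pairs (population κ ≈ 0.71) and runs
the full pipeline:

```
simulated 60 experiments, 1097 foci
FWE threshold 0.182 (1051 voxels survive)
nodes: ['Hipp_L_1', 'Hipp_R_1', 'Amyg_L_1', 'ParaHipp_L_1', 'ParaHipp_R_1',
        'TempInf_L_1', 'TempInf_R_1', 'Precun_R_1']
significant edges (kappa, posterior P(kappa>0)):
  Hipp_L_1 -- Amyg_L_1: kappa=0.706 P=1.0000  [planted]
  Hipp_R_1 -- ParaHipp_R_1: kappa=0.860 P=1.0000  [planted]
  ParaHipp_L_1 -- TempInf_L_1: kappa=0.653 P=1.0000  [planted]
population kappa of planted pairs: 0.708
```

Eight of the ten regions yield nodes (the 90th-percentile peak filter drops
the two with weakest convergence), three of the four planted couplings are
recovered as significant edges with κ̂ near the population value, and no
spurious edge appears among the 28 candidate pairs.

The other examples demonstrate single capabilities: `02_patel_kappa.py`
(κ and its Monte-Carlo significance on 2×2 tables), `03_ale_mapping.py`
(ALE + FWE thresholding), `04_topology.py` (degree/betweenness/k-core/
hemisphere split/region merging).

A thin CLI mirrors the library:

```bash
coalternet simulate --out data --seed 0
coalternet run --foci data/foci.txt --atlas data/atlas.nii.gz \
    --labels data/labels.tsv --out results --seed 0
coalternet topo --network results/network.graphml --out results
```

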