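# cohortnet

Multilayer network analysis of layered cohort data: mutual-information
network construction with permutation significance, signed Boolean dynamics
under noisy periodic forcing, cross-correlation path identification between
biological layers, and degree-preserving permutation negative controls.

## The problem

Multimodal cohort studies of neurodegeneration collect data at several
biological scales for the same subjects — genetics, molecular markers (e.g.
CSF proteins), PET metabolism, MRI morphometry, risk factors and symptoms,
and cognitive/clinical phenotypes. Each scale is one *layer* of a multilayer
network whose nodes are variables; the analysis question is how a
perturbation at a deep layer (a genotype, a metabolic change) propagates
through the network and shows up in the clinical phenotype. `cohortnet`
implements that analysis as a tested, reusable pipeline for anyone with a
subjects × variables table and a variable → layer assignment, and ships a
synthetic cohort generator with planted ground truth so every stage is
verifiable without access to patient data.

## The method

1. **Edges.** For every variable pair, the plug-in binned mutual information
   `I(X;Y) = Σ_ij p(i,j) log[p(i,j)/(p_x(i)p_y(j))]` (nats) is estimated on
   the pairwise-complete subjects; significance comes from a permutation test
   (1000 label shuffles, α = 0.05). Significant within-layer and inter-layer
   pairs become edges weighted by the normalized MI
   `NMI = I/√(H_x H_y) ∈ [0,1]`, giving one global multilayer network with no
   predefined hierarchy. A companion *signed* network over all layers uses
   the Pearson coefficient (two-tailed permutation test) so each edge is
   activating (r > 0) or inhibitory (r < 0).
2. **Connectivity.** Layer structure is summarised by the connectance matrix:
   within-layer weighted density `d = 2Σw / (|V|(|V|−1))` on the diagonal and
   bipartite density `d_bip = Σw / (|V_i||V_j|)` off it, plus the average
   shortest path length with distance = 1/weight.
3. **Dynamics.** Binary node states update synchronously on the signed
   network: a node activates iff the signed weighted sum of its *active*
   neighbours is positive. One input node is clamped to a square wave
   (10 steps on / 10 off) for 100 steps; each other node flips its state with
   probability 0.05 per step — without that noise strongly coupled nodes lock
   active and connection strength becomes invisible.
4. **Paths.** Every network edge gets the maximal lagged cross-correlation
   `cc` between its endpoints' activity traces; a path's score is the sum of
   `1/cc` along its edges (low score = few hops, strong coupling). The ten
   lowest-score loopless paths from each input to each phenotype target are
   extracted with Yen's algorithm over Dijkstra.
5. **Controls.** Each identified path is re-sought in degree-preserving
   permuted networks (double edge swaps with rejection, 10 attempts per edge,
   weights re-shuffled; simulations re-run identically). Paths that reappear
   as top paths in < 1% of permuted networks are flagged as specific.

## Worked example

`examples/05_path_identification.py` plants a genetic → PET → risk →
phenotype chain (shared latent factor, loading 0.7) in a six-layer synthetic
cohort of 1,000 subjects, infers the signed network and extracts the top-10
paths from the chain's source to its phenotype target:

```
signed network: 58 nodes, 113 edges
top-10 paths genetic_004 -> phenotype_004 (score = sum of 1/cc; lower = stronger):
   1. score   5.87  genetic_004 -> phenotype_004
   2. score   9.96  genetic_004 -> PET_008 -> phenotype_004
   3. score  10.14  genetic_004 -> risk_002 -> phenotype_004
   4. score  11.70  genetic_004 -> risk_002 -> PET_008 -> phenotype_004
   5. score  15.19  genetic_004 -> PET_008 -> risk_002 -> phenotype_004  <- planted chain
   ...
```

All pairs of chain members share the chain's latent factor, so the direct
edge and the two-hop shortcuts legitimately outscore the full planted
sequence; the planted four-node chain is still recovered inside the top ten,
and `examples/06_permutation_controls.py` shows it surviving the negative
control (never a top path in 20 degree-preserving permuted networks).
`examples/04_boolean_simulation.py` prints the forcing wave and a leaf's
trace — an exact one-step-delayed copy — and shows how 5% noise widens the
cross-correlation distribution (sd 0.000 → 0.033 on a star network), which
is what makes coupling strengths rankable.

The other examples cover cohort generation, pairwise association statistics,
the connectance matrix and focal-node connectivity summaries.

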