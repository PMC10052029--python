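# kinetraj

Comparative analysis of molecular-dynamics trajectories for protein kinases
and similar two-lobe systems: structural stability, correlated motions,
collective-coordinate free-energy landscapes, Markov-state-model kinetics,
binding-energy bookkeeping, and residue community networks — the toolchain a
computational chemist reaches for when asking *why does this inhibitor lock
one kinase isoform's phosphate-binding loop (P-loop) closed but not the
other's?*

Because multi-microsecond production trajectories are rarely shippable, the
package also contains a first-class synthetic-system module that plants
recoverable ground truth — metastable multi-well dynamics, block-structured
displacement covariances, discrete Markov chains, additive energy tables,
and a two-lobe bead protein whose loop folds over a ligand — so every
analysis stage can be validated end to end against known answers.

## What it computes

| Stage | Quantity |
|---|---|
| `stability` | Kabsch superposition, per-frame RMSD, per-residue RMSF about the iterated mean structure |
| `correlation` | DCCM: C<sub>ij</sub> = ⟨Δr<sub>i</sub>·Δr<sub>j</sub>⟩ / (⟨Δr<sub>i</sub>²⟩⟨Δr<sub>j</sub>²⟩)<sup>1/2</sup>, with a \|C\| < 0.3 display mask and region-block summaries |
| `collective` | PCA of RMS-fitted coordinates; free-energy landscapes G<sub>i</sub> = −k<sub>B</sub>T ln(N<sub>i</sub>/N<sub>m</sub>); loop–ligand distances; porcupine vector fields |
| `msm` | K-means microstates, transition-matrix estimation (raw / reversible), implied timescales t<sub>i</sub> = −τ/ln\|λ<sub>i</sub>(τ)\|, Chapman–Kolmogorov test, PCCA+ metastable states, mean first passage times |
| `energetics` | MM/GBSA-style combination ΔG<sub>bind</sub> = ΔE<sub>elec</sub> + ΔE<sub>vdW</sub> + ΔG<sub>pol</sub> + ΔG<sub>np</sub> (+ΔE<sub>internal</sub>; −TΔS omitted), per-residue decomposition with a 1 kcal/mol significance threshold, geometric H-bond occupancy |
| `network` | Contact edges (4.5 Å for ≥ 75 % of frames), d<sub>ij</sub> = −ln\|C<sub>ij</sub>\| weights, Girvan–Newman communities, betweenness-weighted intercommunity pathway strengths |

`kinetraj.pipeline.run_pipeline` chains the stages over one system and
`compare_systems` tabulates the deltas between two systems (apo vs. bound,
isoform vs. isoform).

## Worked example

`examples/08_compare_open_closed.py` builds two synthetic systems from the
same two-lobe loop protein — one whose loop dwells open, one whose loop stays
folded onto the ligand bead — runs the full pipeline on both and compares:

```
loop-ligand distance change (closed - open): -14.8 A
loop RMSF change (closed - open): -1.41 A
open  : 0 loop-hinge contact edges, community link: None
closed: 8 loop-hinge contact edges, community link: (2, 3, 99.0)
-> closure shortens the distance, damps the loop, and opens a
   loop-to-hinge communication pathway
```

Loop closure shows up exactly as it does in real inhibitor-bound kinase
trajectories: the loop approaches the ligand (distance mean drops ~15 Å),
its fluctuations are damped (RMSF down 1.4 Å), and the contact network gains
a loop-to-hinge intercommunity connection (communities 2 and 3 joined with
betweenness strength 99) that the open system lacks.

The other scripts in `examples/` each demonstrate one capability —
trajectory IO, RMSD/RMSF, DCCM recovery of planted ±0.9/−0.2 blocks, PCA +
free-energy landscapes, MSM estimation and validation, binding-energy
combination and decomposition, and community detection — each printing the
planted truth next to the recovered value.

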