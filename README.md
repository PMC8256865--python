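# fusiongrn

Root-centred gene regulatory network (GRN) analysis for fusion-protein-
driven leukemia.

Chromosomal fusion proteins such as KMT2A-AFF1 rewire transcription both
by direct promoter binding and indirectly through intermediate
transcription factors (TFs) such as RUNX1. `fusiongrn` reconstructs and
interrogates that regulatory hierarchy from three evidence layers:
knockdown (KD) differential-expression tables, ChIP-seq binding, and a
curated TF-interaction catalog. It is aimed at computational biologists
studying regulator-centred transcriptional programs who want the whole
workflow — network construction, centrality and perturbation analysis,
signed motif classification, and patient-cohort subnetwork activity — as
tested, composable library code with a thin CLI.

## What it computes

**Network construction.** Nodes are restricted to KD-responsive genes
(FDR < 0.05); `direct` edges come from root ChIP peaks annotated to their
nearest promoter (optionally enhancer-filtered: H3K27ac ∩ H3K4me1,
≥ 1 bp); catalog edges are admitted between in-scope genes and the graph
is pruned to the subgraph reachable from the root. Edge signs follow the
KD response of the target: logFC < 0 under regulator KD ⇒ activation
(`+`), logFC > 0 ⇒ repression (`−`).

**Centrality and in-silico deletion.** Degree (in + out) and Shimbel
stress centrality — for node *v*, the number of shortest directed paths
σ<sub>st</sub>(v) over all ordered pairs s ≠ v ≠ t whose interior
contains *v*. Deleting a node *x* in silico (no re-pruning) yields a
per-gene stress fold change

FC(g) = log₂((stress_after(g) + 1) / (stress_before(g) + 1)),

with mean |FC| ranking regulators by how much regulatory traffic they
reroute.

**Signed motifs.** Given GRNs for the fusion root A and an intermediate
TF B with A → B activating, each shared target closes a feed-forward
loop, classified C1/C3 (coherent) or I1/I3 (incoherent) from the sign
quadrant of its two KD responses; B-only targets form coherent or
incoherent cascades.

**Patient subnetworks.** A cohort TPM matrix induces one subnetwork per
sample (scope ∩ expressed genes, thresholded at each cohort's mean
log₂(TPM+1)); node presence gives a binary activity matrix, per-cohort
conservation percentages, and k-means activity clusters (k = 5).

**Synthetic data.** A generator plants all of the above — networks with
known edges and signs, motif subtypes, activity programs, essentiality
categories — plus decoy peaks and catalog edges that every filter must
remove, so the whole pipeline is testable end to end with no downloads.

## Worked example

```python
import fusiongrn as fg

params = fg.preset("small", seed=7)
data = fg.generate_dataset(params)          # synthetic inputs + truth

grn = fg.build_root_grn(data)               # 4-step construction
print(grn)

print(fg.centrality_report(grn).head(5).to_string(index=False))

analysis = fg.run_motif_analysis(data)      # integrate A- and B-GRNs
print(analysis.summary.to_dict())

imp = fg.deletion_impact(grn, data.truth.intermediate)
print(f"mean |stress FC| after deleting RUNX1: {imp.mean_abs_fc:.4f}")
```

Output:

```
GRN(root='KMT2A-AFF1', nodes=59, edges=78)
   gene_id  degree  stress
     RUNX1      40      27
      TF01       5       8
      TF02       5       8
KMT2A-AFF1      31       0
     G0001       2       0
{'counts': {'C1': 8, 'C3': 4, 'I1': 6, 'I3': 2, 'coherent': 14, 'incoherent': 5},
 'ffl_total': 20, 'cascade_total': 19,
 'ffl_coherent_pct': 60.0, 'cascade_coherent_pct': 73.7, 'cascade_incoherent_pct': 26.3}
mean |stress FC| after deleting RUNX1: 0.1093
```

Reading this: the intermediate TF (RUNX1) is the highest-degree,
highest-stress non-root node — it carries the indirect layer — while the
root itself has zero stress (nothing routes *through* a source). Of the
20 feed-forward loops recovered in this small noisy instance, 60% are
coherent (the two regulators push the target the same way); 73.7% of
cascades agree in sign. Deleting RUNX1 shifts mean |stress FC| by 0.11
log₂ units across the network, the largest single-node perturbation.

The same steps are available from the shell:

```bash
fusiongrn simulate --seed 7 --preset small --out-dir data/
fusiongrn centrality --graph grn.tsv --metric stress --top 10
fusiongrn perturb --graph grn.tsv --delete RUNX1
fusiongrn motifs --grn-a grn.tsv --grn-b grn_b.tsv --kd-a kd_root.tsv --kd-b kd_intermediate.tsv
```

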