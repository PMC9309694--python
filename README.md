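# cernet

Inference of lncRNA–miRNA–mRNA competing-endogenous-RNA (ceRNA) networks from
two-group RNA-seq count data, built around the study design of an age-related
erectile dysfunction (A-ED) versus negative-control (NC) rat experiment.  The
package is aimed at transcriptomics analysts who want the full chain — raw-read
QC, normalization, differential expression, correlation screening, the
hypergeometric sponge test, network export, gene-set enrichment and the
phenotype/qPCR arithmetic — as tested, composable Python functions plus a thin
CLI, with a synthetic-data generator that plants a known truth network for
validation.

## The method

Under the ceRNA hypothesis, a lncRNA sharing miRNA response elements with an
mRNA sponges those miRNAs and de-represses the mRNA.  Candidate pairs are
screened over differentially expressed features (NB exact conditional test,
|log2FC| > 2, p < 0.05 for miRNA/mRNA):

1. keep predicted (miRNA, target) pairs with Spearman correlation SCC < 0;
2. keep (lncRNA, mRNA) pairs sharing a surviving miRNA with Pearson
   correlation PCC > 0.5;
3. with N differentially expressed miRNAs in the universe, K sponged by the
   lncRNA, n targeting the mRNA and x shared, retain the pair iff the
   hypergeometric upper tail is below 0.05:

   p = Σ_{i=x}^{min(K,n)} C(K,i) C(N−K, n−i) / C(N,n)

Retained pairs form a tripartite network (lncRNA–miRNA "sponge" edges,
miRNA–mRNA "represses" edges) exportable to GraphML/SIF for Cytoscape.  The
same exact hypergeometric tail drives gene-set over-representation (Fisher
exact, top-20 reporting).  See `docs/methods.md` for the model, assumptions
and numerical choices.

## Worked example

```python
from cernet import simdata, cerna

cfg = simdata.SimulationConfig(seed=1)          # 20 planted ceRNA modules
lnc, mir, mrna, truth = simdata.simulate_counts(cfg)
targets = simdata.simulate_target_table(cfg, truth)

result = cerna.run_pipeline(lnc, mir, mrna, targets)
found = {(p.lncrna, p.mrna) for p in result.pairs}
tp = len(found & truth.planted_pairs)
print(len(result.pairs), tp, result.network.number_of_nodes())
print(cerna.pair_table(result.pairs).head(3).to_string(index=False))
```

prints

```
25 19 55
   lncrna      mrna                           shared_mirnas  x  K  n  N      pcc  p_sponge
LNC000001 MRN000001 MIR000001,MIR000002,MIR000014,MIR000017  4  4  4 17 0.872773  0.000420
LNC000001 MRN000018                     MIR000002,MIR000017  2  4  2 17 0.909687  0.044118
LNC000002 MRN000002           MIR000002,MIR000008,MIR000011  3  4  3 17 0.942124  0.005882
```

25 lncRNA–mRNA pairs pass all three screens, 19 of them planted truth; each
row shows the shared sponge miRNAs, the overlap bookkeeping (x of K/n in a
universe of N = 17 differentially expressed miRNAs), the co-expression PCC
and the sponge-test p.  The equivalent shell pipeline:

```sh
cernet simulate --seed 1 --out sim/
cernet cerna --lnc-counts sim/lnc_counts.tsv --mir-counts sim/mir_counts.tsv \
             --mrna-counts sim/mrna_counts.tsv --samples sim/samples.tsv \
             --targets sim/targets.tsv --out network
```

Other entry points: `cernet filter-reads` (adapter / >10% N / >50% Q<=20
rules), `cernet de`, `cernet enrich`, `cernet pheno` (ICP/MAP grouping at
0.35), `cernet qpcr` (2^-ddCt against beta-actin).

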