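# respmr

Integrative analysis of interindividual transcriptional response to glucose
and genetic association, as a tested, reusable pipeline:

1. **Response testing** (`respmr.response`) — per-individual glucose response
   (`delta = mean HG − mean SG` over replicates, log2 scale), empirical-Bayes
   moderated one-sample (all individuals) and two-group differential tests,
   BH FDR, detection filtering, inter- vs intra-individual variance rank test
   and PCA/covariate QC.
2. **Preranked GSEA** (`respmr.gsea`) — ranking by `sign(effect) ×
   −log10(p)`, weighted running-sum enrichment score, gene-set permutation
   null, NES and sign-stratified FDR.
3. **Storey π1** (`respmr.pi1`) — π0/π1 estimation with a λ tuning grid
   (cubic-polynomial smoother, fixed-λ fallback for small sets).
4. **eQTL–GWAS enrichment** (`respmr.enrichment`) — eSNP collection at an
   FDR cap, eGene over-representation, GWAS p-value enrichment (proportion
   below α, BH within the set, Bonferroni threshold, λ_GC, QQ points) and a
   random-eGene permutation null.
5. **Summary-data Mendelian randomization** (`respmr.mr`) — SMR
   (`b_xy = b_zy/b_zx`, χ²₁ statistic), HEIDI heterogeneity test with
   delta-method covariance under LD, multi-SNP SMR with a weighted-χ² null,
   plus LD computation, greedy r² pruning and proxy search.
6. **Synthetic data** (`respmr.simulate`) — genotype panels with AR(1)
   latent-Gaussian LD, a paired SG/HG expression study (22 individuals:
   7 nDM / 7 nDR / 8 PDR, 3 replicates × 2 conditions) and eQTL/GWAS summary
   statistics under a liability-threshold disease model in which risk is
   mediated through the expression of designated genes — with full ground
   truth, so every stage is testable offline.
7. **Pipeline + CLI** (`respmr.pipeline`, `respmr.cli`) — end-to-end
   orchestration with plain TSV/JSON stage outputs and a machine-readable
   report.

## CLI

```sh
# full synthetic run: simulate -> respond -> GSEA -> enrichment -> MR
respmr run-all --seed 7 --out runs/demo

# or stage by stage
respmr simulate --seed 7 --out runs/demo
respmr respond --expression runs/demo/expression.tsv --out runs/demo
respmr gsea --results runs/demo/response_all.tsv --gmt sets.gmt --out runs/demo/gsea.tsv
respmr enrich --eqtl runs/demo/eqtl.tsv --gwas runs/demo/gwas.tsv \
              --genes runs/demo/top_diff_genes.txt --out runs/demo/enrichment.json
respmr mr --eqtl runs/demo/eqtl.tsv --gwas runs/demo/gwas.tsv \
          --panel runs/demo/panel.tsv --gene G00000 --out runs/demo/mr.json
```

`run-all` also accepts a YAML config (`--config`) with an `out_dir`, a
`simulation` block (any `SimulationConfig` field) or input `paths`
(expression/eqtl/gwas/panel TSVs, optional GMT and truth JSON), and a
`thresholds` block (response p cut, eQTL FDR, GWAS α, r² prune/proxy,
permutation counts). Exit codes: 0 ok, 2 config error, 3 data error.

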