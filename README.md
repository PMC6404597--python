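# crossgrm

Genomic relationship matrices for multi-line intercross pedigrees —
autosomes and X chromosome.

## The problem

Experimental populations such as selection lines and advanced intercross
lines (AIL) descend from a handful of founders drawn from two or more
genetically distinct lines. Pedigree relationship matrices that treat those
founders as unrelated and non-inbred mis-scale the genetic variance: loci
fixed for alternative alleles in the parental lines start segregating in
the F2 and contribute *segregation variance* that pedigree data alone
cannot quantify. When all founders are genotyped, the observed line allele
frequencies determine expected genomic relationships for every descendant,
restoring a well-defined base population (the unrelated, non-inbred F2) and
with it interpretable variance components — on the X chromosome as well,
where hemizygous males need their own transmission rules.

`crossgrm` is for quantitative geneticists analyzing line crosses: it turns
a founder genotype file plus a pedigree into the matrices a mixed-model
analysis needs.

## The method

For marker *i* with line frequencies *p<sub>iℓ</sub>* and line weights
*w<sub>ℓ</sub>* (uniform by default), the composite frequency is
*p̄<sub>i</sub> = Σ<sub>ℓ</sub> w<sub>ℓ</sub> p<sub>iℓ</sub>* and the scale
is *S = 2 Σ<sub>i</sub> p̄<sub>i</sub>(1 − p̄<sub>i</sub>)*.

* **Observed founder matrix** `G0 = Z0 Z0′ / S`, where Z0 holds gene counts
  centered by 2p̄ (autosomes, X females) or p̄ (hemizygous X males).
* **Gamete moments** `d_ℓ = Σ_i [p_iℓ(1−p_iℓ) + (p_iℓ−p̄_i)²] / S` and
  `r_ℓm = Σ_i (p_iℓ−p̄_i)(p_im−p̄_i) / S` give the **expected founder
  matrix** `E(G0)` (autosomal self 2d+2r, within-line 4r, between-line
  4r_ℓm; X entries scale with the number of X copies each sex carries).
  For two lines with uniform weights, `d_A + d_B = 1` and
  `r_AA = r_BB = −r_AB`; the proportion of genetic variance that is
  segregation variance is `−2 r_AB`.
* **Tabular extension** propagates the founder matrix to all descendants
  (`Ã` when seeded with `E(G0)`): autosomal diagonal
  `s_sire + s_dam + ½ g(sire,dam)`, off-diagonals averaging the parents'
  rows; on the X, females add the *whole* paternal term and males carry
  only the maternal one (`g_kk = s_dam`).
* **Combination** `H⁻¹ = Ã⁻¹ + [G0_BLD⁻¹ − E(G0)⁻¹]` on the founder block,
  with `G0_BLD = 0.98·G0 + 0.02·E(G0)` restoring invertibility when G0 is
  singular. The `Dk = mean diag − mean` founder-block correction re-scales
  estimated variance components to the unrelated-base definition.
* **Gene-drop** Monte Carlo (Mendelian sampling at independent loci, with
  the X-specific rules) provides the simulation oracle the analytic
  matrices are validated against.

Any number of founder lines and unequal contributions are supported through
the definition of p̄.

## Worked example

Generate a two-line AIL fixture (4 control-line males × 4 high-line
females, 5 generations) and run the pipeline:

```sh
crossgrm fixture --out-dir demo --lines "FL:0:4,CT:4:0" --freq-model uniform \
    --n-autosomal 200 --n-x 60 --template ail --generations 5 \
    --litter-size 6 --seed 4
crossgrm moments --pedigree demo/pedigree.csv --genotypes demo/founders.csv
```

```
# partition: autosomal
S	79.5703125
d_FL	0.50284732449680902
d_CT	0.49715267550319098
r_FLFL	0.11698576337751596
r_CTFL	-0.11698576337751596
r_CTCT	0.11698576337751596
```

`d_FL + d_CT = 1` and `r_FLFL = r_CTCT = −r_CTFL` are the two-line
identities; `−2 r_CTFL ≈ 0.234` says ~23% of the F2 genetic variance of
this synthetic cross is segregation variance. The full pipeline

```sh
crossgrm run --pedigree demo/pedigree.csv --genotypes demo/founders.csv \
    --outdir demo/out
```

writes `G0`, `E(G0)`, the blended founder matrix, `Ã` and `H⁻¹` for both
partitions plus a report:

```
rank_G0_autosomal	7
Dk_autosomal	1.134489445262641
segregation_proportion	0.2339715267550319
```

(The observed 8×8 G0 is singular — rank 7 — which is why the blended matrix
feeds the H⁻¹ assembly; `Dk ≈ 1.13` would multiply a genetic variance
estimated with this H.) `Hinv_*.txt` are lower-triangle triplet files ready
for mixed-model solvers that accept user-defined inverse covariance
structures.

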