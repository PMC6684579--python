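# tritrend

Three-condition comparison of label-free skin proteomes — healthy (**H**),
non-lesional (**NL**) and lesional (**L**) psoriatic skin — with composite
differential-expression testing and a fold-change *trend taxonomy* that asks,
per protein, where the non-lesional level sits between healthy and lesional.

It is written for proteomics analysts who start from protein-level
quantification tables (MS1 intensities and/or spectral counts, proteins in
rows) of a pooled-replicate design, and want reproducible per-contrast DE
calls, trend categories, enrichment, and a planted-truth simulator for
validating the whole chain.

## The method

For each pairwise contrast (L vs H, NL vs H, NL vs L) and each protein *g*,
three p-value channels are computed:

1. **Moderated t** on log2 intensities. The pooled per-protein variance
   s²_g (residual df *d_g*) is shrunk toward a prior variance s₀² with prior
   df *d₀*, both estimated across all proteins by the method of moments on
   the log sample variances (empirical Bayes):

       s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)
       t̃_g  = (x̄_A − x̄_B) / √(s̃²_g (1/n_A + 1/n_B)),   t̃_g ~ t(d_g + d₀)

2. The same moderated t on variance-stabilized spectral counts,
   log2(count + c) with pseudocount c = 0.5.

3. **Rank product** on the per-replicate intensity log2 fold changes:
   RP_g = (∏_r rank_{g,r})^{1/k} over the k replicate experiments, with a
   permutation null (each replicate's rank column permuted independently;
   exact enumeration when feasible, otherwise seeded Monte Carlo with
   p = (b+1)/(B+1)); up- and down-regulation tails are combined two-sidedly.

A protein is **differentially expressed (DE)** in a contrast when
min p < α (default 0.05, raw — a Benjamini–Hochberg column is written for
information only) **and** its ratio-scale fold change FC = x̄_num/x̄_den
satisfies FC ≥ 2 or FC ≤ 0.5.

The three contrasts are then combined per protein into trend flags, with
T = log2 2 = 1:

| flag | definition | reading |
| --- | --- | --- |
| `intermediate` | DE in L vs H and \|log2FC(NL/H)\| < T and \|log2FC(NL/L)\| < T | NL is a transitional stage |
| `group_I` | DE in NL vs H and \|log2FC(NL/L)\| < T | lesional-like change already in NL (predisposing) |
| `group_II` | DE in NL vs L and not DE in L vs H | NL-characteristic alteration |
| `group_III` | DE in NL vs L and sign(log2FC(NL/H)) ≠ sign(log2FC(L/H)) | opposite-direction change (maintenance) |
| `lesion_only` | (DE in L vs H or NL vs L) and not DE in NL vs H | altered only where lesions are involved |

Flags are independent booleans (the categories genuinely overlap). The DE
fold gate is inclusive (exactly 2-fold counts as changed) while the
"within two-fold" band is strict, so a ratio of exactly 2 is DE-eligible but
never "similar".

A generic hypergeometric over-representation analysis (background = all
quantified proteins) with BH q-values replaces service-based enrichment, and
a four-process intersection screen reports "central regulator" candidates
annotated to all four supplied processes.

## Worked example

The classic psoriasis biomarker panel (AKR1B10, CSTA, FABP5, PI3, the S100
family, SCCA2, STAT1/3) ships with the package as fold-change triplets with
their published significance marks:

```python
import tritrend as tt

fixture = tt.load_table2_fixture()            # 11 (protein_id, TriContrast)
flags = tt.classify_table([tc for _, tc in fixture])
print(flags.loc[["AKR1B10", "CSTA", "FABP5"],
                ["de_LH", "intermediate", "lesion_only", "unclassified_divergent"]])
print(tt.summarize_categories(flags))
```

prints

```
            de_LH  intermediate  lesion_only  unclassified_divergent
protein_id
AKR1B10      True         False         True                    True
CSTA         True          True         True                   False
FABP5        True         False         True                    True

{'n_proteins': 11, 'n_de_LH': 11, 'n_de_NLH': 0, 'n_de_NLL': 4,
 'n_intermediate': 1, 'intermediate_fraction_of_de_LH': 0.0909...,
 'n_group_I': 0, 'n_group_II': 0, 'n_group_III': 0,
 'n_lesion_only': 11, 'n_unclassified_divergent': 10, ...}
```

Every biomarker is strongly up in lesional skin (`de_LH`); none is called in
NL vs H, so all 11 are lesion-associated. Only CSTA (2.335-fold up in L,
with NL at 1.752× of H and 0.75× of L — within two-fold of both) is
*intermediate*; the other ten change far more in lesions than in
non-lesional skin and are flagged as divergent.

The same taxonomy runs end to end from matrices:

```sh
tritrend simulate --out-dir sim --seed 7
tritrend run --config run.yaml          # normalize -> 3 contrasts -> classify -> enrich
```

writing `results_{LH,NLH,NLL}.tsv`, `flags.tsv`, `summary.tsv` and a
`manifest.json` that makes the run byte-reproducible.

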