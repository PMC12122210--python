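# varhomol

Pathogenicity annotation transfer between **homologous missense variants** —
variants occupying the same column of a protein-family multiple sequence
alignment in different proteins.

## The problem

Of the millions of missense variants seen in human exomes, only a small
fraction carry a clinical annotation, which limits diagnosis in rare
Mendelian disease. For proteins whose genes follow autosomal-dominant (AD)
inheritance, a single damaging substitution correlates directly with the
clinical phenotype, and equivalent positions across homologous proteins tend
to share the consequence of equivalent substitutions. `varhomol` exploits
this: it maps annotated variants onto curated family seed alignments
(Stockholm format, Pfam `name/start-end` headers), enumerates *homologous
variant pairs*, measures how often their annotations agree, and transfers
labels to unannotated variants.

Two variants at one alignment column form a pair in one of four categories,
based on BLOSUM substitution scores (two residues are *similar* when their
score is strictly positive):

| mode           | reference residues | alternate residues |
|----------------|--------------------|--------------------|
| `strict`       | identical          | identical          |
| `similar_mut`  | identical          | similar            |
| `similar_ref`  | similar            | identical          |
| `similar_both` | similar            | similar            |

Pair concordance (both non-pathogenic N-N, both pathogenic P-P, discordant
N-P) is scored directionally: each member of a pair serves once as truth and
once as transferred prediction, so a concordant pair contributes 2 TP or
2 TN and a discordant pair exactly one FN plus one FP. From these counts the
package reports sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy,
and the Matthews correlation coefficient
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

Prediction is two-staged: homolog evidence decides whether a variant is
**damaging** (alters protein structure/function); only in a *pathogenic
protein* — an AD gene with ≥3 distinct pathogenic missense variants — does
damaging translate to **disease-causing**. A damaging variant in a recessive
or X-linked gene is called non-disease-causing, since it can persist in the
healthy population.

## Worked example

The classic illustration is a sodium-channel pore domain: `SCN4A` p.N440K
(paramyotonia congenita) and `SCN5A` p.N406K (cardiac channelopathy)
co-align at one column of the ion-transport family domain.

```python
import varhomol as vh

sto = """\
# STOCKHOLM 1.0
#=GF AC PF00520
SCN4A/438-442  QWNDE
SCN5A/404-408  QWNDL
//
"""
(fam,) = vh.parse_stockholm(sto)
annotated = [vh.MissenseVariant("SCN5A", 406, "N", "K", label="pathogenic",
                                source="clinvar", origin="germline")]
proteins = {"SCN4A": vh.ProteinRecord("SCN4A", inheritance="AD", n_pathogenic_missense=5),
            "SCN5A": vh.ProteinRecord("SCN5A", inheritance="AD", n_pathogenic_missense=5)}

clf = vh.HomologousTransferClassifier(alignments=[fam], proteins=proteins).fit(annotated)
(pred,) = clf.predict_detail([vh.MissenseVariant("SCN4A", 440, "N", "K")])
```

which prints, via the fields of `pred`:

```
damaging call : damaging
clinical call : disease_causing
evidence      : SCN5A p.N406K (pathogenic, tier=strict, identity=0.80)
```

The query maps to the same column as an annotated pathogenic homolog with
identical reference and alternate residues (a *strict* match at 80% segment
identity), so the substitution is predicted damaging; because SCN4A is an AD
gene with an established pathogenic missense burden, the clinical verdict is
disease-causing.

The same logic is available from the shell. A complete synthetic run:

```bash
varhomol fixtures --outdir fx --seed 5 --n-columns 60
varhomol evaluate --alignments fx/alignment.sto --clinvar fx/clinvar.tsv \
                  --gnomad fx/gnomad.tsv --proteins fx/proteins.tsv --outdir ev
```

`ev/metrics.tsv` then holds one row per pair mode × identity stratum with
class counts, raw metrics, and two-decimal display values. Other
subcommands: `build` (dataset filters + manifest), `pairs` (pair table),
`predict` (batch queries → JSON/TSV), `expand` (project one annotated
variant onto all homologous positions).

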