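# nucleopart

Quantification of nuclear and nucleolar protein partition in trypanosome
micrographs, with the protein-sequence analyses that explain it.

## The problem

In *Trypanosoma brucei*, as in other eukaryotes, proteins reach the nucleus
through a nuclear localisation signal (NLS) — here the canonical monopartite
motif **K-R-X-R** — while accumulation in the nucleolus has no consensus
signal and instead tracks positive charge: basic residue content, high
isoelectric point (pI), and basic intrinsically disordered regions (IDRs).
Testing this quantitatively needs two things: a per-cell measurement of how
a fluorescent reporter partitions between cytoplasm, nucleoplasm and
nucleolus in thousands of cells, and sequence-level descriptors of charge
and motif content for the tagged proteins. `nucleopart` provides both as a
tested, reusable library, and ships a ground-truth phantom generator so
every stage is verifiable without any raw microscopy download.

## What it computes

**Imaging side.** From three-channel widefield images (phase contrast,
Hoechst DNA stain, mNeonGreen reporter; 0.103 μm/px):

1. flat-field correction by subtracting the per-session median image;
2. cell segmentation from phase contrast — sequential Gaussian unsharp
   filters (radii 1, 6, …, 31 px, weight 0.4), threshold at mean − 1 s.d.,
   objects of 2000–7000 px² whose darkest pixel is ≥ 2 s.d. under the mean;
3. DNA-object detection — 1 px blur, 15 px rolling-ball background
   subtraction, local maxima with prominence > 1.5× image s.d., each grown
   to its connected region above 0.4× the peak;
4. kinetoplast/nucleus (K/N) assignment from the object count per cell
   (2 → 1K1N, 3 → 2K1N, 4 → 2K2N; the largest object(s) are the nuclei —
   the kinetoplast divides first in the trypanosome cell cycle);
5. nucleus radius *r* = mean of the fitted ellipse axes; the nucleolus is
   the darkest DNA-channel point at least *r*/8 from the nucleus edge,
   modelled as a disc of radius *r*/4;
6. per-cell partition ratios of mean reporter signal —
   nucleus/cytoplasm and nucleolus/nucleoplasm — aggregated per cell line,
   filtered for expression, and classified (nucleolar / nucleoplasmic /
   nuclear / cytoplasmic) against configurable cutoffs.

**Sequence side.** Residue-class composition (charged RHKDE, hydrophobic
AILMFWYV, polar STNQ, basic KRH, acidic DE), molecular mass, pI by
bisection of the Henderson–Hasselbalch net charge, overlapping KRXR motif
scanning with N-/C-terminal proximity (whole motif within 15 residues of a
terminus), IDR segmentation (disorder score > 0.5), the Das–Pappu
diagram-of-states classification from (f⁺, f⁻), and per-protein 20-residue
composition matrices (optionally with the first 30 residues trimmed, to
discount mitochondrial targeting presequences).

**Statistics.** Wilcoxon rank-sum / signed-rank group comparisons, Pearson
chi-squared 2×2 enrichment tests, Benjamini–Hochberg adjustment on request,
and report tables that keep N- and C-terminal tagging evidence as
independent rows with a protein-level rollup.

## Worked example

```python
from nucleopart import (PhantomSpec, make_phantom_field, segment_micrograph,
                        measure_cell, aggregate_line, classify_localisation,
                        ClassificationThresholds, composition_profile,
                        ProteinRecord, MNEONGREEN)

spec = PhantomSpec(n_cells=9, reporter_conc=(1.0, 4.0, 8.0),
                   shot_noise=False, read_noise_sd=0.0, seed=100)
micrograph, truth = make_phantom_field(spec)
cells = []
for seg in segment_micrograph(micrograph):
    if not seg.excluded:
        cells.append(measure_cell(seg.cell_mask,
                                  [n.mask for n in seg.nuclei],
                                  seg.nucleolus_masks,
                                  micrograph["reporter"]))
summary = aggregate_line(cells, line_id="phantom", terminus="N")
print(summary.n_cells, summary.mean_ratio_nc, summary.mean_ratio_nn)
print(classify_localisation(summary, ClassificationThresholds(2.0, 2.0)))

mng = composition_profile(ProteinRecord(id="mNG", sequence=MNEONGREEN))
print(mng.frac_negative, mng.frac_positive, mng.pI)
```

prints

```
cells measured:        9
mean ratio N/C:        4.000
mean ratio No/Np:      2.000
classification:        ['nuclear', 'nucleolar']
mNG acidic fraction:   10.6%
mNG basic fraction:    13.6%
mNG isoelectric point: 7.22
```

The phantom was built with reporter concentrations (1, 4, 8) in cytoplasm,
nucleoplasm and nucleolus, so the recovered mean ratios of 4.0 and 2.0 are
exactly the ground-truth concentration ratios; with both ratios above the
2.0 cutoffs the line classifies as nuclear and nucleolar. The mNeonGreen
reporter itself is charge-balanced (10.6% acidic vs 13.6% basic residues,
pI 7.22) — a neutral control that stays pan-cellular unless an NLS or a
basic tract is fused to it.

A command-line interface mirrors the library:

```bash
nucleopart simulate images  --spec spec.yaml --seed 1 --out fields/
nucleopart simulate proteome --seed 1 --out proteome.fasta
nucleopart segment  --in fields/ --out seg/
nucleopart quantify --in fields/ --out quant/ --line-id myline
nucleopart seqprops --fasta proteome.fasta --out props.tsv
nucleopart report   --lines quant/per_line.tsv --seq props.tsv --out report.tsv
```

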