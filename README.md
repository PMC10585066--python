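# thermoscore

Ranking crop cultivars by heat tolerance from physiology and transcriptomics.

Screening cultivars for thermotolerance is slow when it relies on whole-season
field performance. `thermoscore` implements a seedling-stage inference chain
developed for tomato: quantify heat damage physiologically, compare the
heat-shock transcriptome of tolerant and sensitive cultivars, explain the
differences through promoter cis-elements, and distill the result into a small
panel of expression biomarker genes whose stress-time expression scores any
new cultivar's tolerance. A synthetic-study generator with recorded ground
truth makes the whole chain testable end to end.

The package is aimed at plant stress physiologists and regulatory-genomics
analysts working with replicate log2 expression tables (microarray or qPCR),
1-kb upstream promoter FASTA, and simple physiological measurements.

## The statistics at the core

**Composite physiological index.** For each cultivar c, after/before-stress
ratios of Fv/Fm (maximum quantum yield of photosystem II), root weight and
shoot weight, plus the mean leaf wilting index (LWI, ~1 for unwilted plants),
are each z-scored across cultivars: z_c = (x_c − x̄)/s (sample SD, ddof = 1).
The index is the unweighted mean of the four z-scores; the extremes define
the most tolerant and most sensitive cultivars.

**Heat induction.** Per gene and cultivar, log2 induction = mean log2(stress)
− mean log2(control), with a two-sided Welch t-test across replicates. Genes
are called up/down at |log2FC| ≥ 1 and p < 0.05 (configurable), regulated
sets are compared by Venn overlap, and differential induction between two
cultivars is flagged at a twofold (1 log2 unit) difference with a Welch test
on per-replicate induction contrasts.

**Cis-element enrichment.** Promoters are scanned for five degenerate
elements — complete HSE (nGAAn)(nTTCn)(nGGAn), partial HSE (nGAAn)(nTTCn),
DRE A/GCCGAC, ABRE ACGTGG/T, EE AAAATATCT — counting all overlapping
occurrences (motif n = any base; an N in the sequence matches nothing).
Enrichment of an element in a focal set (the top-100 upregulated genes) is

    z = (N − μ) / σ

where N is the observed total count in the focal promoters and μ, σ are the
mean and SD of that total over 1000 random 100-gene sets drawn from the full
promoter universe.

**Biomarker panel and scoring.** Candidate biomarkers must satisfy three
strict log2 criteria against a tolerant (AT) and sensitive (SF) reference:
induction in AT > 6; AT-over-SF stress-level ratio > 1.4; absolute AT stress
level > 12. Each panel gene's stress-time expression is z-scored across
cultivars, and a cultivar's score is the mean z over the panel; Spearman rank
correlation quantifies concordance with the physiological index.

## Worked example

```python
import thermoscore as ts
from thermoscore.cisenrich import MOTIF_REGISTRY

study, promoters, physio, truth = ts.simulate_study(seed=7)

idx = ts.composite_index(ts.parameter_ratios(physio))
print(idx.ranking)                       # ['AT', 'Mm8', 'Sat', 'RGL', 'SF']

tab = ts.induction(study, ("acute_50", 1.0), ("control_25", 0.0))
top100 = ts.top_n_upregulated(tab, "AT", 100)
r = ts.enrich(top100, promoters, MOTIF_REGISTRY["partial_HSE"],
              set_size=100, reps=1000, seed=7)
print(f"z={r.z:.2f} N={r.n_observed} mu={r.mu:.1f} sigma={r.sigma:.2f}")
# z=20.97 N=176 mu=38.6 sigma=6.55

panel = ts.select_candidates(tab, "AT", "SF")
scores = ts.score_cultivars(study, panel.genes, ("acute_50", 1.0))
print(scores.ranking)                    # ['AT', 'Mm8', 'Sat', 'RGL', 'SF']
print(round(ts.concordance(scores, idx), 3))  # 1.0
```

The physiological index and the biomarker score independently recover the
planted tolerance order (AT most tolerant, SF most sensitive); the partial
HSE is heavily over-represented in the acute-shock top-100 promoters
(observed 176 sites against a null of 38.6 ± 6.6, z ≈ 21); and the two
rankings agree perfectly (Spearman ρ = 1).

The same chain is available from the shell:

```bash
thermoscore run-all --seed 7 --outdir out/
thermoscore enrich out/promoters.fasta --genes top100.txt --motif EE \
    --reps 1000 --seed 7 --out enrich.tsv
```

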