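# snapscreen

Analysis pipeline for **structure-comparison ELISA binding screens**:
plate-based chemiluminescence assays in which a library of FLAG-tagged
proteins (delivered as whole-cell lysates) is probed against two immobilized
nucleic-acid structures — a test structure such as a PNA:DNA:PNA
heterotriplex or a TFO-induced DNA triplex, and a reference structure such
as the same-sequence DNA duplex. The scientific question is *which proteins
recognize the unusual structure specifically*, i.e. bind the test structure
above background and more strongly than the duplex control.

The package is for screen analysts: it takes plate maps, raw plate-reader
luminescence exports and a library annotation table, and produces hit calls,
QC reports and enrichment statistics. A seeded synthetic-screen generator
with planted ground truth supports validation and power analysis.

## Model and statistics

For every well, raw luminescence (RLU) is log2 transformed. Each physical
plate carries empty background wells (no tagged protein); their log2 signal
defines a per-plate background with mean μ_bg and sample SD σ_bg, and every
well on that plate is standardized:

    z = (log2 RLU − μ_bg) / σ_bg

Per-plate standardization cancels plate-to-plate multiplicative effects
exactly. Replicate z-scores are averaged per factor and condition, giving
z_dup (reference) and z_tri (test), and the differential-binding statistic

    Δz = z_tri − z_dup

Hit calling uses fixed dual thresholds, both inclusive:

* **recruited**: max(z_dup, z_tri) ≥ 5
* among recruited — **test-selective** if Δz ≥ 2.5,
  **reference-selective** if Δz ≤ −2.5, else **recruited-nonselective**

Around the core statistic the package provides: replicate QC by OLS
regression of replicate-2 on replicate-1 z-scores (R², zero-slope p);
negative/positive control checks; exact one-sided hypergeometric tests of
hit frequency per library category (DNA repair / chromatin-associated /
other); a Δz-ranked waterfall table with log2 fold-change tie-breaks; and
ChIP-qPCR percent-input quantification, `100 · 2^(adjusted input Ct − IP Ct)`
with dilution-adjusted input Ct and fold enrichment over the averaged mock
condition.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
520-factor screen (336 DNA-repair, 64 chromatin-associated, 120 other
control factors; biological duplicates of duplex and triplex conditions on
384-well plates; 126 planted binders of which 16 triplex-selective and 17
duplex-selective):

```bash
python analysis/01_simulate_screen.py --seed 1
python analysis/02_score_screen.py    --seed 1
python analysis/03_qc_enrichment.py   --seed 1
python analysis/04_chip_validation.py --seed 1
```

Step 02 prints the recovered partition and its agreement with the planted
truth:

```
recovered partition:
{
  "library_size": 520,
  "recruited": 126,
  "test_selective": 19,
  "reference_selective": 17,
  "recruited_nonselective": 90,
  "not_recruited": 394,
  "recruitment_rate_pct": 24.23076923076923
}
planted partition: {'not_recruited': 394, 'recruited_nonselective': 93,
                    'reference_selective': 17, 'test_selective': 16}
per-factor agreement with ground truth: 0.9942
```

All 126 planted binders are recovered as recruited (24.2% of 520). Three
nonselective binders drift across the Δz = 2.5 line into the test-selective
class — the irreducible consequence of thresholding a duplicate-screen Δz
whose noise SD is ≈1 z-unit (see `docs/methods.md`). Step 03 prints the QC
and enrichment readout:

```
replicate R^2 (all, n=1040): 0.818 (p = 0.00e+00)
replicate R^2 (test-selective, n=38): 0.917
control GFP [negative]: pass   control XPA [positive]: pass   control RPA2 [positive]: pass
            category   n  k  expected direction  p_value
          dna_repair 336 93 81.415385  enriched 0.008108
chromatin_associated  64 18 15.507692  enriched 0.263444
       other_control 120 15 29.076923  depleted 0.000278
```

The non-chromatin control category carries 15/120 hits (12.5%) against an
expectation of 29.1, a depletion the exact hypergeometric test flags at
p = 2.8×10⁻⁴ — structure binders concentrate among chromatin-handling
proteins. Step 04 quantifies a synthetic ChIP-qPCR validation: the target
locus shows 10.0-fold enrichment under anti-FLAG IP in structure-treated
cells, and ≈1.0 in every mock, IgG and off-target condition.

The same pipeline is available as a CLI for real exports:

```bash
snapscreen validate --plate-map M.csv --readings R.csv --library L.csv
snapscreen run --plate-map M.csv --readings R.csv --library L.csv --outdir out/
```

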