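# ctdnamon

Circulating tumor DNA (ctDNA) analysis for monitoring neoadjuvant
chemotherapy (NACT) in gastric cancer, from duplex-barcode molecule grooming
through longitudinal response metrics and survival stratification — packaged
with a synthetic cfDNA cohort generator so the entire chain runs and is
tested without any patient data.

## The problem

In stage II–III gastric cancer, two cycles of NACT precede gastrectomy, and
only a minority of patients respond. Plasma cell-free DNA (cfDNA) sampled
before chemotherapy (P0), after chemotherapy (P1) and after surgery (P2)
carries a tumor-derived fraction whose variant allele frequencies (VAFs) sit
near or below 0.1%, so calling it requires aggressive error suppression:

1. **Molecule grooming** — raw ~5000× reads are grouped into unique source
   molecules by mapping position + bi-barcode pair; a duplex decoder rejects
   molecules whose two strands disagree (`ctdnamon.groom`).
2. **Panel-of-normals background model** — healthy-donor plasma pools give a
   per-(position, substitution) background allele fraction and maximal
   distinct-molecule support; a candidate is kept only if it is
   significantly above background on *both* axes: exact one-sided binomial
   tail p < α on the allele fraction, and support strictly above the
   normals' maximum (`ctdnamon.errordb`).
3. **Positivity calling** — after germline/clonal-hematopoiesis filtering
   against the patient's white-blood-cell control, a plasma variant is
   positive if support ≥ 3 and total ≥ 100 when the variant is known mutant
   in the patient's tumor tissue (tissue-informed), or support ≥ 6 and
   total ≥ 100 otherwise; a sample is ctDNA-positive iff it has ≥ 1 passing
   somatic variant (`ctdnamon.calls`).
4. **Monitoring** — per timepoint: max-VAF and number of genomic alterations
   (GAs); between timepoints: Δmax-VAF = max-VAF(P1) − max-VAF(P0),
   ΔGAs likewise, and the four-way clearance class of the status pair;
   cohort level: detection rates, tissue/plasma concordance, gene-level
   alteration frequencies (`ctdnamon.monitor`).
5. **Statistics** — Wilcoxon signed-rank / rank-sum for paired and
   between-group comparisons, t-test/ANOVA, chi-square/Fisher, Kaplan–Meier
   estimation and the Gehan–Breslow–Wilcoxon (GBW) weighted log-rank
   (weight = number at risk) for survival by ctDNA status
   (`ctdnamon.stats`).

`ctdnamon.simcohort` generates the truth world these stages consume: panel,
per-site background error rates, patient variant sets with the observed
tissue/plasma overlap structure (33.8% shared / 56.2% tissue-only / 9.5%
plasma-only), per-response-class VAF trajectories (partial response
declining, stable disease flat, progressive disease rising), read-family
tables at duplex-barcode resolution, healthy-donor pools, and exponential
survival with a hazard ratio tied to post-NACT ctDNA detectability.

## Worked example

```python
from ctdnamon.simcohort import SimulationConfig
from ctdnamon.workflows import analyze_cohort
from ctdnamon.stats import gbw_test, km_estimate

res = analyze_cohort(SimulationConfig(seed=1))   # 79 patients, 3 timepoints
for tp in ("P0", "P1", "P2"):
    d = res.detection(tp)
    print(tp, f"{d.n_positive}/{d.n_total} = {d.rate_pct}%")

groups = res.survival_groups("P1")
for label, recs in groups.items():
    km = km_estimate(recs, group=label)
    print(label, f"3-year OS = {km.survival_at(36):.2f}")
print("GBW p =", round(gbw_test(groups).p_value, 3))
```

prints

```
P0 53/79 = 67.1%
P1 39/79 = 49.4%
P2 37/79 = 46.8%
negative 3-year OS = 0.73
positive 3-year OS = 0.43
GBW p = 0.025
```

Detection declines from baseline through surgery; patients still
ctDNA-positive after chemotherapy have markedly worse 3-year overall
survival (43% vs 73%), and the GBW comparison flags the separation —
the qualitative structure the monitored cohort shows.

The same analysis is available as a file-based pipeline with a manifest and
per-stage outputs (TSV/VCF/JSON):

```bash
ctdnamon run-all --config examples/cohort.yaml --outdir runs/demo
```

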