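# serialcoal

Serial-coalescent simulation and the bias of neutrality tests under
heterochronous sampling — with the divergence statistics used on ancient
mtDNA haplotype groups.

## The problem

Ancient-DNA datasets are *heterochronous*: samples are radiocarbon-dated to
different ages, so the tips of their genealogy enter the coalescent at
different depths. Classical summary-statistic tests of demographic change —
Tajima's *D* and Fu's *Fs* — assume all samples are contemporaneous
(*isochronous*). Both statistics have expectation ≈ 0 under a constant-size
neutral population and become strongly negative under demographic expansion,
which also produces star-like genealogies. When serially sampled sequences
are pooled and analysed as if contemporaneous, the extra time separating old
and young tips inflates rare variants and haplotype counts, mimicking
exactly that expansion signature.

`serialcoal` quantifies this artefact. It provides:

* **`sim_core`** — a serial-coalescent genealogy simulator (lineages enter
  at their tip ages; pairs coalesce at rate C(j,2)/N(t)) under constant or
  exponentially changing haploid demography N(t) = N₀·e^(−g·t), with a
  transition-biased finite-sites (or infinite-sites) mutation overlay.
  Defaults emulate a 37-tip Holocene mtDNA collection: 360-bp sequences,
  mutation rate 7.6×10⁻⁷/site/year, generation time 7 years, Ti/Tv = 50.
* **`neutrality`** — Tajima's *D* = (π − S/a₁)/√(e₁S + e₂S(S−1)), Fu's
  *Fs* = ln(S′/(1−S′)) with S′ = P(K ≥ k_obs | θ̂=π, n) from the Ewens
  sampling formula (log-space Stirling numbers), and empirical significance
  against isochronous constant-size coalescent nulls conditioned on the
  observed number of segregating sites.
* **`bias_pipeline`** — the scenario grid (HET vs IS sampling × Ne ∈ {500,
  2000, 10000} × g ∈ {0, 0.001, 0.01}, 1,000 replicates per cell) with
  per-cell means, empirical 95% intervals, percent-significant tails, and
  box-plot data export.
* **`empirical_divergence`** — pairwise difference counts, two-level AMOVA
  Φst with permutation tests and bootstrap standard errors, and classical
  (Torgerson) MDS of a Φst distance matrix, for real alignments read from
  FASTA + metadata CSV.

## Worked example

```python
from serialcoal import (Demography, SampleSchedule, Scenario, run_scenario)

het = SampleSchedule.default_heterochronous()   # 37 tips, 2,000..12,000 yr BP
iso = SampleSchedule.isochronous(37)

for name, sched in [("HET", het), ("IS", iso)]:
    sc = Scenario(scheme=name, demography=Demography(N0=500, g=0.0),
                  schedule=sched, n_reps=1000, seed=11, null_seed=99)
    r = run_scenario(sc)
    print(f"{name}: mean D = {r.mean('D'):+.2f}, mean Fs = {r.mean('Fs'):+.2f}, "
          f"Fs %significant-negative = {r.pct_sig_neg('Fs'):.1f}")
```

prints

```
HET: mean D = -1.08, mean Fs = -5.71, Fs %significant-negative = 58.4
IS: mean D = -0.04, mean Fs = -0.00, Fs %significant-negative = 3.6
```

Both runs use a *constant* population size — the strongly negative D and Fs
under HET are generated purely by the temporal spread of the samples. The
isochronous control behaves as the neutral theory predicts (means near zero,
~5% false-positive rate per tail).

The same machinery is available from the shell:

```bash
serialcoal scenario --scheme HET --ne 500 --out het.csv
serialcoal grid --out grid.csv --boxplot-out boxes.csv
serialcoal phist alignment.fasta metadata.csv
serialcoal mds phist_matrix.csv
```

## Notes

See `docs/methods.md` for the model, the numerical choices, and the known
limitations — in particular what the default evenly spaced age fixture does
and does not represent.
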