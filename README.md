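# capsip

Detection of ¹³C-labeled taxa in RNA stable-isotope-probing (SIP)
experiments by **comparative amplicon sequencing** (CAP-SIP), together with
the surrounding bookkeeping a substrate-tracing microcosm study needs:
synthetic SIP-gradient and process-chemistry simulation, gradient-fraction
classification and OTU-table handling, and isotope carbon/electron mass
balances.

## Who this is for

Microbial ecologists running (or planning) RNA-SIP time courses: a
¹³C-labeled substrate (here: chitin, the GlcNAc polymer) is fed to a soil
community under oxic or anoxic conditions; organisms that assimilate
substrate carbon synthesize isotopically heavy RNA, which migrates to
denser fractions of an isopycnic density gradient. Amplicon libraries from
pooled "heavy" (buoyant density 1.81–1.83 g ml⁻¹) and "light"
(1.76–1.77 g ml⁻¹) fractions of ¹³C- and ¹²C-substrate treatments are then
compared to decide, per OTU and time point, whether the taxon is labeled.

## The statistic

For an OTU at time point *t_x*, let

* *R_a* — relative abundance (%) in heavy fractions, ¹³C treatment, *t_x*
* *R_b* — heavy fractions, ¹²C treatment, *t_x*
* *R_c* — light fractions, ¹³C treatment, *t_x*
* *R_d* — heavy fractions, ¹³C treatment, *t₀*

The significance threshold *T* is estimated from the *t₀* baseline: the
mean per-OTU difference *R_heavy,13C − R_heavy,12C* plus three times its
sample standard deviation (a 3σ rule; under Gaussian noise the implied
correct-detection rate is 2Φ(3) − 1 = 99.73%). An OTU is scored labeled at
*t_x* when, with strict inequalities,

1. *R_a − R_b > T*
2. *R_a − R_c > T*
3. *R_a − R_d > T*
4. *R_cs > T* (reported; not required for the verdict), where
   *R_cs = (3·R_a − R_b − R_c − R_d)/3* is the per-OTU labeling magnitude
   ("average relative CAP-SIP abundance").

Note that *R_cs* is exactly the mean of the three criterion margins, so
criteria 1–3 jointly imply criterion 4. Labeled verdicts are additionally
required to replicate on ≥ 2 distinct days (configurable).

The mass-balance side converts GC-MS 45/44 ion ratios (after indoor-air
background correction) to ¹³C atom fractions, and computes carbon recovery
(cumulative ¹³CO₂ over supplied ¹³C) and electron recovery (degree-of-
reduction-weighted products plus Fe(II), over electrons in the substrate;
the GlcNAc residue C₈H₁₃NO₅ carries 8 C and 32 e⁻ per mole).

## Library quick start

```python
import numpy as np
from capsip import CapSipClassifier

rng = np.random.default_rng(0)
baseline = np.abs(rng.normal(1.0, 0.2, size=(100, 2)))      # t0 heavy 13C/12C
clf = CapSipClassifier().fit(baseline)                      # threshold_ = mean + 3 SD
quads = np.array([[5.0, 1.0, 1.0, 1.0],                     # R_a, R_b, R_c, R_d
                  [1.0, 0.9, 0.8, 0.9]])
clf.predict(quads)            # array([ True, False])
clf.decision_function(quads)  # R_cs scores: array([4. , 0.13...])
```

`CapSipClassifier` follows the scikit-learn estimator protocol
(`get_params`/`set_params`, fitted attributes `mean_diff_`, `sd_diff_`,
`threshold_`), so it composes with sklearn tooling. The module functions
(`compute_baseline`, `call_labels`, `replication_filter`,
`cumulative_rcs`, …) operate on `AbundanceTable` objects read from TSV.

## Worked example (CLI)

`capsip` ships a subcommand pipeline. With this `demo.yaml`:

```yaml
seed: 4
gradient:
  oxic:
    n_otus: 40
    reads_per_library: 2000
    labeled_otus:
      1: {3: 1.0, 10: 1.0, 21: 1.0, 70: 0.8}   # OTU id -> day -> atom fraction
      2: {10: 0.8, 21: 1.0, 70: 1.0}
  anoxic:
    n_otus: 40
    reads_per_library: 2000
    labeled_otus:
      2: {10: 0.6, 21: 1.0, 70: 1.0}
```

```sh
capsip simulate   -c demo.yaml   # gradient tables + process series (TSV)
capsip call-labels -c demo.yaml  # thresholds, per-OTU calls, summary.json
capsip mass-balance -c demo.yaml # carbon/electron recoveries per day
capsip report     -c demo.yaml
```

prints (abridged):

```
== oxic treatment ==
baseline mean 7.77e-13% (SD 0.258%), threshold T = 0.774%
  day 3: 1 labeled, cumulative R_cs = 95.2%
  day 10: 2 labeled, cumulative R_cs = 96%
  day 21: 2 labeled, cumulative R_cs = 95.9%
  day 70: 2 labeled, cumulative R_cs = 95.9%
labeled OTUs (R_cs % by day):
day     3.0   10.0  21.0  70.0
OTU_01 95.20 51.63 26.86 13.95
OTU_02     - 44.34 69.06 81.92
recoveries:
 day  carbon_recovery_percent  electron_recovery_percent
   3                  10.5061                          0
  21                  54.0217                          0
  70                  92.4980                          0
```

Reading it: the simulated t₀ baseline noise (SD 0.26%) gives a 3σ
threshold of 0.77%; the OTU injected as fully labeled from day 3 (OTU_01)
is called on all four days with an R_cs that decays as the second labeled
OTU takes over — the cross-feeding succession pattern CAP-SIP is designed
to resolve. Under the oxic process defaults (pure respiration,
first-order rate 0.037 d⁻¹), 54% of the supplied chitin carbon is
recovered as ¹³CO₂ by day 21; oxic electron recovery is zero by
construction because respiration hands its electrons to O₂, which the
inventory does not track.

Each command writes a manifest (config echo, versions, input checksums,
seed); reruns with the same config and seed are byte-identical apart from
the manifest timestamp.

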