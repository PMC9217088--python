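# paleotroph

Trophic-level reconstruction from the nitrogen isotopes of shark tooth
enameloid, for stable-isotope paleoecologists working on million-year
timescales where collagen is gone.

Tooth enameloid is a hypermineralized tissue whose small organic fraction
survives diagenesis. Its nitrogen isotope ratio (δ15N_EB, ‰ vs. air) rises
with trophic level the way other animal tissues do:

    δ15N_tissue(TL) = δ15N_baseline + (TL − 1) · TDF

with TDF the trophic discrimination factor (~2.3–5.5‰ per step for shark
tissues). `paleotroph` implements the full chain from raw nanomole-scale
isotope analyses to ecological inference:

* **reduction** — two-point calibration against nitrate reference materials
  (IAEA-NO3 4.7‰, USGS34 −1.8‰), oxidation-blank δ15N estimated by mass
  balance from amino-acid references (USGS40 −4.5‰, USGS65 20.68‰),
  blank correction, N content (μmol N/g), and batch QC statistics;
* **tissue ground-truthing** — errors-in-variables (Deming) regression of
  δ15N_EB on dentin collagen δ15N with bootstrap CIs, Pearson correlation
  test, and the EB−dentin tissue offset;
* **trophic reconstruction** — species × epoch means referenced to the
  pooled contemporaneous piscivorous sharks (anchored at trophic level
  4.4), Δδ15N / TDF trophic offsets with propagated errors, diet δ15N
  (EB − 1.7‰ − 2.5‰), Welch tests, and diagenesis / baseline-consistency
  screens;
* **body size** — position-specific linear crown-height → total-length
  functions with a conservative selection rule for ambiguous teeth;
* **literature comparison** — n-weighted placement of diet δ15N against
  compiled modern shark and marine-mammal δ15N observations;
* **synthetic data** — a seeded generator reproducing the statistical
  structure of such datasets (trophic chain, tissue offsets, biological
  scatter, measurement noise, oxidation blanks, allometry), so every stage
  is testable against known truth.

## Worked example

Ground-truth the enameloid-bound signal on 13 simulated modern sand tiger
teeth carrying both tissues (`examples/02_tissue_ground_truthing.py`):

```
$ python examples/02_tissue_ground_truthing.py
13 paired modern teeth (generated with slope 1, offset 1.7 permil)
Deming: d15N_EB = 1.03 [0.46, 1.51] x d15N_dentin + 1.0 [-6.0, 9.7] permil
Pearson r = 0.77, t = 3.96, df = 11, p = 0.0022
tissue offset (EB - dentin): 1.5 +/- 0.7 permil
```

The Deming slope CI spans 1 and the offset sits near the generating 1.7‰:
enameloid-bound nitrogen records the same dietary signal as the established
dentin collagen recorder, shifted by a fixed tissue offset. Then reconstruct
trophic levels against the piscivore baselines
(`examples/03_trophic_reconstruction.py`):

```
  Miocene: d15N_EB 23.7 permil, delta vs piscivores +6.8 +/- 1.6 permil
           -> trophic level 7.1 (TDF 2.5), diet d15N 19.5 permil, Welch p = 8.3e-14
 Pliocene: d15N_EB 23.7 permil, delta vs piscivores +7.4 +/- 1.7 permil
           -> trophic level 7.4 (TDF 2.5), diet d15N 19.5 permil, Welch p = 2.7e-11
```

A ~7‰ elevation over contemporaneous fish-eating sharks is ~3 trophic
steps at a TDF of 2.5‰ — a predator feeding well above any piscivore, at
trophic positions scarce in modern oceans. `examples/` contains one short
script per capability; each prints its numbers with a line on what they
mean.

The same stages are available as a CLI for file-based work:

```sh
paleotroph simulate --seed 0 --out-dir sim
paleotroph reduce --raw sim/raw_analyses.csv --out reduced.csv --qc qc.csv
paleotroph run --seed 0 --out-dir full_run    # all six stages + manifest
```

Column layouts are documented in `docs/schemas.md`; the model, parameter
defaults and their rationale in `docs/methods.md`.

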