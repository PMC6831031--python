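# helipol

Orientation and translocation-polarity analysis for hexameric replicative
helicases on fork DNA.

Ring-shaped helicases such as the archaeal MCM hexamer encircle one strand
of a replication fork and translocate 3'→5', excluding the other strand.
Each subunit has an N-terminal DNA-binding lobe (NTD) and a C-terminal
AAA+ motor lobe (CTD), so a hexamer can sit on the fork in two
orientations — NTD nearest the duplex junction (**N@duplex**) or CTD
nearest it (**C@duplex**) — and can lead with either face during
unwinding (**N-first** vs **C-first**). `helipol` implements the
quantitative pipeline that resolves both questions from four assay
streams, for biochemists analysing gel densitometry and stopped-flow
kinetics of helicase–fork complexes:

1. **Footprint densitometry.** A cleavage probe conjugated near the CTD
   cuts the labelled strand close to wherever the C-terminal face sits.
   With the single-strand window split into a junction-proximal region
   (assigned N@duplex) and a junction-distal region (C@duplex), the
   orientation fractions are

   *F*ₓ = (*S*ₓ − control) / [(*S*_N − control) + (*S*_C − control)],  X ∈ {N, C},

   computed per replicate lane and compared by a two-tailed equal-variance
   two-sample *t*-test.

2. **Single-turnover unwinding.** With ATP plus excess trap DNA each
   hexamer acts once, so the unwound fraction saturates at the fraction of
   productively oriented complexes. Band intensities are normalized
   between zero-time and boiled controls,

   *F*(*t*) = [*r*(*t*) − *r*(0)] / [*r*(b) − *r*(0)],  *r* = *I*ₛ/(*I*ₛ + *I*_d),

   and fit to *F*(*t*) = *A*_f (1 − e^(−*kt*)); the amplitude *A*_f **is**
   the productive fraction.

3. **Equilibrium binding.** Anisotropy titrations are fit to the Hill
   isotherm *Y* = *A*_max [P]ⁿ / (*K*_dⁿ + [P]ⁿ).

4. **Stopped-flow FRET.** Presteady-state traces on a split time base are
   fit to *v*(*t*) = Σᵢ *a*ᵢ e^(−*k*ᵢ*t*) + *C* (1–3 exponentials, signed
   amplitudes; *a* < 0 is a signal increase). With a streptavidin roadblock
   stalling the helicase near the FRET reporter, the slow phase rises only
   when the dye sits on the leading face — a direct read-out of
   translocation polarity.

The `inference` stage integrates the streams: a *z*-test checks that the
unwinding amplitude matches the footprint fraction of one orientation (and
not its complement), and the blocked-trace sign pattern must name the same
leading face. Two concordant streams yield an `N_first` or `C_first`
verdict; anything less is `indeterminate`.

A mechanistic synthetic-data generator (`helipol.simulate`) produces all
four data streams from a known binding-population ground truth, so every
stage has a parameter-recovery test surface and the end-to-end verdict can
be shown to discriminate N-first from C-first truths.

## Worked example

Simulate the full study design for the 3'-long-arm fork substrate under an
N-first ground truth, then run each stage:

```sh
helipol simulate --preset fork_3long --truth N_first --seed 11 --out demo
helipol footprint --manifest demo/lanes_manifest.yaml --out demo/fp.json
helipol unwind --input demo/unwinding_rep1.csv --out demo/uw.json
helipol infer --dir demo --out demo/verdict.json
```

which prints:

```
wrote simulated datasets to demo
F_N = 0.569 ± 0.002 (***); call: N_at_duplex_preferred
productive fraction 0.565 ± 0.006, k = 0.0679 min^-1
  fork_3long: amplitude matches F_N (z=0.99) not F_C (z=20.81)
  FRET: blocked slow phase rises for N label, decrease for C label
verdict: N_first
```

Reading the output: the footprint stage recovers the generating N@duplex
population (0.57) with a significant orientation preference; the
single-turnover amplitude (0.565) statistically matches F_N but not the
C@duplex complement (z = 20.8 ≫ 1.96); and the blocked stopped-flow slow
phase rises only for the N-terminal dye. Both evidence streams name the
N-terminal face as leading, so the verdict is `N_first` — the direction
the data were generated under.

The same stages run from the library (`helipol.simulate_cleavage_profiles`,
`helipol.analyze_replicates`, `helipol.fit_timecourse`, `helipol.fit_hill`,
`helipol.fit_multi_exponential`, `helipol.classify_translocation_direction`)
for scripted use.

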