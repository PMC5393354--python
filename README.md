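# epid2dose

Convert raw cine-mode images from an amorphous-silicon flat-panel EPID
(electronic portal imaging device) into **absolute 2D dose distributions in
water** at the depth of dose maximum, and compare dose maps with
**γ-index analysis** — the workflow behind EPID-based patient-specific QA of
modern radiotherapy deliveries (IMRT/VMAT/SBRT, WFF and FFF beams, small
fields).

An EPID is not water-equivalent: its scintillator response and optical glare
make raw pixel values an indirect fluence measure. `epid2dose` implements the
physics chain that fixes this:

1. **Pixel-response correction** — dark-field (DF) and flood-field (FF) cine
   stacks calibrate per-pixel offset and gain:

       corrected(x,y) = (raw − DF̄) / (FF̄ − DF̄)

   followed by a multiplicative beam-profile matrix that restores the
   open-beam structure (WFF "horns", FFF cone) that flood normalisation
   removes, and robust dead-pixel masking.

2. **Fluence reconstruction** — the corrected image is the incident primary
   photon fluence Ψₚ blurred by the detector glare kernel K_de; Ψₚ is
   recovered by Wiener-regularised deconvolution:

       Ψₚ(x,y) = corrected(x,y) ⊗⁻¹ K_de(x,y)

3. **Dose conversion** — Ψₚ is convolved with a water pencil-beam dose
   kernel K_pb (generated in-package by a photon Monte Carlo in water under
   the kerma approximation) to the relative dose at d_max:

       D_w(x,y) = Ψₚ(x,y) ⊗ K_pb(x,y)

   and scaled to cGy with an absolute factor from a 100 MU reference
   delivery, F_ABS = 100 cGy / D_EPID.

4. **γ-index QA** — per-pixel γ with global dose-difference normalisation, a
   10 %-of-maximum low-dose threshold, sub-pixel distance-to-agreement
   search, and pass-rate reports at 3%/3mm, 2%/2mm, 1%/1mm.

A full **synthetic forward simulator** (field apertures with penumbra,
per-pixel gain/dark structure, Poisson and read noise, cine framing) provides
ground truth for every stage, so the whole inverse chain is testable without
a linac.

## Worked example

`examples/03_reconstruct_absolute_dose.py` calibrates a simulated panel,
derives F_ABS from a 100 MU reference delivery of the 10×10 cm² field, and
reconstructs two further deliveries:

```
F_ABS (6MV_WFF)    : 0.3345 cGy per relative-dose unit
reference delivery CAX :   99.79 cGy  (expected 100)
half-MU delivery CAX   :   50.04 cGy  (expected 50)
dose profile FWHM      : 99.2 mm (field size 100 mm)
```

The central-axis dose of an independently acquired identical delivery comes
back at 100 cGy within the counting noise, the half-MU delivery at 50 cGy
(MU linearity), and the reconstructed profile width matches the field size.
`examples/05_gamma_qa.py` runs a 7-segment MLC plan end to end and prints the
QA table:

```
         label criterion  pass_rate_pct  n_evaluated
7-segment plan    3%/3mm      99.968214         6292
7-segment plan    2%/2mm      99.745709         6292
7-segment plan    1%/1mm      95.708837         6292
```

The other examples cover calibration (`01`), kernel generation and Monte
Carlo bookkeeping (`02`), and output-factor recovery (`04`). A thin CLI
(`epid2dose calibrate / make-kernel / simulate / reconstruct / gamma`)
wraps the same functions for shell use.

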