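# SYNTHETIC default panel — plausible placeholders, not measured values.
# Receptor abundances are receptors/cell; affinities are molar K_D.
# kd_betagamma_M: none marks a ligand whose IL-2Rbeta/gamma_c epitope is blocked.
ligands:
  - {name: il2, valency: 1, kd_alpha_M: 1.0e-8, kd_betagamma_M: 5.0e-7}
  - {name: control_ic, valency: 2, kd_alpha_M: 1.0e-8, kd_betagamma_M: 5.0e-7}
  - {name: biased_ic, valency: 2, kd_alpha_M: 1.0e-8, kd_betagamma_M: 3.0e-5}
  - {name: blocked_ic, valency: 2, kd_alpha_M: 1.0e-8, kd_betagamma_M: none}
cells:
  - {cell_type: Treg, r_alpha: 3000, r_betagamma: 700}
  - {cell_type: CD8, r_alpha: 100, r_betagamma: 1500}
  - {cell_type: Tconv, r_alpha: 200, r_betagamma: 800}
infer: [biased_ic]
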