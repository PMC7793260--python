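# Default experiment geometry, fluorophore models and simulation conditions.
# Fluorophore parameters are nominal approximations of the published mKO and
# mCherry excitation/emission behaviour at the two excitation bands used by
# the instrument filters (541/12 nm + 550 LP for the donor channel,
# 587/11 nm + 600 LP for the acceptor channel).
channels:
  donor_excitation_nm: 541.0
  acceptor_excitation_nm: 587.0
windows:            # emission grid per channel: [start, stop, step] in nm
  "541": [550.0, 700.0, 1.0]
  "587": [600.0, 700.0, 1.0]
fluorophores:
  donor:
    name: mKO
    emission_peak_nm: 559.0
    emission_width_nm: 25.0
    emission_skew: 4.0
    relative_excitation: {"541": 0.90, "587": 0.0}
    quantum_scale: 1.0
  acceptor:
    name: mCherry
    emission_peak_nm: 610.0
    emission_width_nm: 30.0
    emission_skew: 2.5
    relative_excitation: {"541": 0.30, "587": 0.95}
    quantum_scale: 1.0
simulation:
  donor_abundance: 1000.0      # arbitrary brightness units per cuvette
  acceptor_abundance: 1000.0
  background_scale: 200.0      # cellular autofluorescence amplitude
  buffer_level: 20.0           # PBS baseline counts
  noise_sigma: 0.01            # Gaussian noise SD as a fraction of peak signal
  replicate_cv: 0.10           # log-normal biological scatter on abundances
calibration:
  kappa: 1.0                   # extinction ratio epsilon_A/epsilon_D at 541 nm
  r0_nm: 6.4                   # Foerster distance of the mCherry/mKO pair
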