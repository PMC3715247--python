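# Default two-layer skin optics for the Monte Carlo simulator.
#
# The scattering coefficient follows a power law mu_s(lambda) =
# mu_s_550 * (550 / lambda)^mu_s_exponent (lambda in nm, mu_s in mm^-1),
# a literature-typical shape for skin in the visible range; the anisotropy
# factor g is held constant.  These are documented package defaults, not
# measured values for any particular subject.
ambient_n: 1.0
epidermis:
  mu_s_550: 25.0        # mm^-1 at 550 nm (reduced scattering ~7.5 mm^-1)
  mu_s_exponent: 1.3
  g: 0.7
  n: 1.4
  thickness_mm: 0.06
dermis:
  mu_s_550: 10.0        # mm^-1 at 550 nm (reduced scattering ~3 mm^-1)
  mu_s_exponent: 1.3
  g: 0.7
  n: 1.4
  thickness_mm: 4.94
photons: 100000          # per wavelength for training-grid generation
seed: 1234
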