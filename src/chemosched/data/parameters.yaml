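# Rate constants (days^-1) for the two-compartment proliferative/quiescent
# cell-cycle model, per tissue.  gamma: proliferation, delta: proliferative
# death, alpha: P->Q transfer, beta: Q->P transfer, lambda: quiescent death.
tissues:
  bone_marrow:
    gamma: 1.470
    delta: 0.000
    alpha: 5.643
    beta: 0.480
    lambda: 0.164
  breast:
    gamma: 0.500
    delta: 0.477
    alpha: 0.218
    beta: 0.050
    lambda: 0.000
  ovarian:
    gamma: 0.6685
    delta: 0.4597
    alpha: 0.2225
    beta: 0.0500
    lambda: 0.0000

# Global treatment configuration.  s (dimensionless chemotherapeutic
# strength) and b (dose-delivery penalty weight) are calibration constants
# of this package, not literature values: results that depend on them are
# calibration-dependent.  They are chosen so that a full-strength 21-day
# course visibly depletes bone marrow and the optimal schedule is an
# interior rest-then-ramp profile rather than a trivial all-on/all-off one.
defaults:
  s: 1.0
  b: 1.0
  T: 21
  dt: 1.0
  actions: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
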