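scenario:
  name: with_epo
  injury_radius: 0.25
  injury_density: null
  C0: 100.0
  U0: 1.0
  horizon: 240.0
  r_max: 5.0
  n_nodes: 200
  rtol: 1.0e-06
  atol: 1.0e-12
  output_dt: 1.0
parameters:
  D_R: 0.02
  D_M: 0.002
  D_F: 0.002
  D_P: 0.08
  delta_R: 0.25
  delta_M: 0.25
  delta_F: 0.3
  delta_P: 0.005
  sigma_R: 0.008
  sigma_M: 0.008
  sigma_F: 0.015
  sigma_P: 0.02
  delta_U: 0.06
  lambda_R: 8.0
  lambda_M: 0.7
  lambda_F: 1.0
  lambda_P: 0.3
  Lambda: 150.0
  alpha: 0.015
  beta_1: 0.3
  beta_2: 0.02
  gamma: 0.02
  nu: 0.015
  mu_SA: 0.01
  mu_DN: 0.06
  tau_1: 12.0
  tau_2: 24.0
  P_c: 0.4
  h_width: 0.0
metadata:
  format: chondrosim-config-1
  parameter_info:
    D_R:
      units: mm^2/h
      provenance: calibrated
      meaning: ROS diffusivity
    D_M:
      units: mm^2/h
      provenance: calibrated
      meaning: DAMP diffusivity
    D_F:
      units: mm^2/h
      provenance: calibrated
      meaning: TNF-alpha diffusivity
    D_P:
      units: mm^2/h
      provenance: calibrated
      meaning: EPO diffusivity
    delta_R:
      units: 1/h
      provenance: calibrated
      meaning: ROS decay rate
    delta_M:
      units: 1/h
      provenance: calibrated
      meaning: DAMP decay rate
    delta_F:
      units: 1/h
      provenance: calibrated
      meaning: TNF-alpha decay rate
    delta_P:
      units: 1/h
      provenance: calibrated
      meaning: EPO decay rate
    sigma_R:
      units: a.u. mm^2/(cell h)
      provenance: calibrated
      meaning: ROS production per catabolic cell
    sigma_M:
      units: a.u. mm^2/(cell h)
      provenance: calibrated
      meaning: DAMP release per necrotic cell
    sigma_F:
      units: a.u. mm^2/(cell h)
      provenance: calibrated
      meaning: TNF-alpha production per catabolic cell
    sigma_P:
      units: a.u. mm^2/(cell h)
      provenance: calibrated
      meaning: EPO production per healthy cell
    delta_U:
      units: 1/h
      provenance: calibrated
      meaning: matrix degradation rate under saturating TNF-alpha
    lambda_R:
      units: a.u.
      provenance: calibrated
      meaning: ROS half-saturation
    lambda_M:
      units: a.u.
      provenance: calibrated
      meaning: DAMP half-saturation
    lambda_F:
      units: a.u.
      provenance: calibrated
      meaning: TNF-alpha half-saturation
    lambda_P:
      units: a.u.
      provenance: calibrated
      meaning: EPO half-saturation
    Lambda:
      units: a.u.
      provenance: calibrated
      meaning: TNF-alpha inhibition constant in EPO production
    alpha:
      units: 1/h
      provenance: calibrated
      meaning: EPOR-active -> healthy reversion rate under EPO
    beta_1:
      units: 1/h
      provenance: calibrated
      meaning: healthy -> catabolic switching rate driven by DAMPs
    beta_2:
      units: 1/h
      provenance: calibrated
      meaning: healthy -> catabolic switching rate driven by TNF-alpha
    gamma:
      units: 1/h
      provenance: calibrated
      meaning: catabolic -> EPOR-active switching rate (delayed by tau_1)
    nu:
      units: 1/h
      provenance: calibrated
      meaning: catabolic apoptosis rate (requires TNF-alpha AND DAMPs)
    mu_SA:
      units: 1/h
      provenance: calibrated
      meaning: EPOR-active apoptosis rate
    mu_DN:
      units: 1/h
      provenance: calibrated
      meaning: necrotic decay-to-inert rate
    tau_1:
      units: h
      provenance: literature-range
      meaning: delay before EPOR expression (8-12 h; upper end)
    tau_2:
      units: h
      provenance: literature-range
      meaning: delay before EPO synthesis onset (20-24 h; fixed at 24)
    P_c:
      units: a.u.
      provenance: calibrated
      meaning: critical EPO level gating the healthy -> catabolic switch
    h_width:
      units: a.u.
      provenance: calibrated
      meaning: smoothing width of the threshold gate (0 = hard switch)
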