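# Perturbation scenario ledger: multiplicative parameter modifications
# composing genotypes and growth conditions.  Grades were selected by
# the deterministic {1,10,25}% sensitivity protocol plus deletion-grade
# reductions and overexpression grades (see docs/methods.md).
version: 1
scenarios:
  wt: null
  cln3:
    modifications:
      k_cln3_syn: 0.5
  whi5:
    modifications:
      whi5_init_concentration: 0.5
  ydj1:
    modifications:
      chap_total: 0.25
  oCLN3:
    modifications:
      k_cln3_syn: 3.0
  oSSA1YDJ1:
    modifications:
      chap_total: 1.5
  x2_7CHP:
    modifications:
      chap_total: 2.0
      k_hsp_basal: 2.0
  fast_growth:
    modifications:
      growth_rate: 1.25
  slow_growth:
    modifications:
      growth_rate: 0.8
  large_v0:
    modifications:
      initial_volume: 1.5
  small_v0:
    modifications:
      initial_volume: 0.67
  PFD:
    substrate: aggregating
  CD:
    substrate: inert
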