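# Default cascade parameterization, relative units.
#
# Mutant GTPase-cycle values respect the relative bounds reported in
# published biochemical assays of KRAS mutants (Gremer et al; Smith et al;
# Hunter et al): total hydrolysis (k_int + k_gap) reduced ~100-800-fold
# versus wild type (mutants are GAP-insensitive, k_gap ~ 0), and RAF-RBD
# affinity lowered (Kd_raf raised) by up to 7-fold.  Exchange rates are
# shared across lines; stimulation acts purely as GEF recruitment
# (k_ex_basal -> k_ex_stim).  None of these numbers are ground truth; the
# test suite relies only on the relative bounds.
reference_line: KRAS_WT
isoforms:
  KRAS_WT:
    k_int: 0.01        # intrinsic hydrolysis, 1/min
    k_gap: 1.0         # GAP-stimulated hydrolysis, 1/min
    k_ex_basal: 0.005  # basal nucleotide exchange, 1/min
    k_ex_stim: 0.05    # EGF-stimulated exchange, 1/min
    kd_raf: 1.0        # RAS-GTP:RAF dissociation constant, relative units
    provenance: wild-type reference (Gremer; Smith; Hunter)
  KRAS_G12C:
    k_int: 0.0101      # 100x reduced total hydrolysis, GAP-insensitive
    k_gap: 0.0
    k_ex_basal: 0.005
    k_ex_stim: 0.05
    kd_raf: 1.3
    provenance: G12C (Hunter)
  KRAS_G12D:
    k_int: 0.00505     # 200x reduced
    k_gap: 0.0
    k_ex_basal: 0.005
    k_ex_stim: 0.05
    kd_raf: 1.9
    provenance: G12D (Hunter)
  KRAS_G12V:
    k_int: 0.00337     # 300x reduced
    k_gap: 0.0
    k_ex_basal: 0.005
    k_ex_stim: 0.05
    kd_raf: 3.2
    provenance: G12V (Hunter; Gremer)
  KRAS_Q61R:
    k_int: 0.00126     # 800x reduced
    k_gap: 0.0
    k_ex_basal: 0.005
    k_ex_stim: 0.05
    kd_raf: 7.0
    provenance: Q61R (Smith)
abundances:  # relative immunoblot scale, wild type == 1 for each component
  KRAS_WT:   {ras_t: 1.0,  braf_t: 0.5, craf_t: 0.5, mek_t: 1.0, erk_t: 1.0}
  KRAS_G12C: {ras_t: 1.4,  braf_t: 0.6, craf_t: 0.5, mek_t: 0.9, erk_t: 1.1}
  KRAS_G12D: {ras_t: 1.0,  braf_t: 0.4, craf_t: 0.5, mek_t: 1.1, erk_t: 0.9}
  KRAS_G12V: {ras_t: 1.3,  braf_t: 0.5, craf_t: 0.5, mek_t: 1.0, erk_t: 1.2}
  KRAS_Q61R: {ras_t: 0.9,  braf_t: 0.5, craf_t: 0.4, mek_t: 1.0, erk_t: 1.0}
cascade_rates:
  a_raf_mek: 20.0  # composite RAF->MEK activation, 1/(min * rel. conc.)
  d_mek: 1.0       # MEK dephosphorylation, 1/min
  a_mek_erk: 1.0   # MEK->ERK activation
  d_erk: 1.0       # ERK dephosphorylation
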