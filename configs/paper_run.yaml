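# Full-scale run configuration: four CoA-bound donors transplanted into
# two FAAL targets, A and T states, 1-degree flag sweep.
#
# Coordinate files are NOT bundled; fetch them first (network required):
#     coaclash fetch 3PBK 5ICR 1PG4 3CW9 3EQ6 5BSR --out data/structures
#
# Domain residue ranges (author numbering) are REQUIRED input and are not
# inferred: curate the N-/C-terminal domain boundaries for each entry
# (e.g. from the entry's domain annotation) before running.  The null
# placeholders below make any un-curated run fail loudly instead of
# silently shifting every downstream count.

structures:
  3pbk:        # EcFAAL, adenylation-competent state (target)
    path: ../data/structures/3pbk.pdb
    chain: A
    n_domain: null        # curate: [[start, end]]
    c_domain: null        # curate: [[start, end]]
  5icr:        # MsFAAL32 (target)
    path: ../data/structures/5icr.pdb
    chain: A
    n_domain: null
    c_domain: null
  1pg4:        # SeACS, CoA-bound donor
    path: ../data/structures/1pg4.pdb
    chain: A
    n_domain: null
    c_domain: null
    ligand: COA
  3cw9:        # Aa4CBL, CoA-bound donor
    path: ../data/structures/3cw9.pdb
    chain: A
    n_domain: null
    c_domain: null
    ligand: COA
  3eq6:        # HsFACL, CoA-bound donor and T-state template
    path: ../data/structures/3eq6.pdb
    chain: A
    n_domain: null
    c_domain: null
    ligand: COA
  5bsr:        # NtCCL, CoA-bound donor
    path: ../data/structures/5bsr.pdb
    chain: A
    n_domain: null
    c_domain: null
    ligand: COA

targets: [3pbk, 5icr]
donors: [1pg4, 3cw9, 3eq6, 5bsr]
states: [A, T]
t_state_template: 3eq6
canonical_donor: 3eq6
correspondence: sequence_alignment   # curated pairs TSVs recommended; see docs
overlap_threshold: 0.25
census_cutoff: 2.5
step: 1.0
out_dir: ../out/paper_run
seed: 0
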