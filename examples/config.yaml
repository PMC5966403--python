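# Example end-to-end configuration: simulate every input, then run all
# analysis stages on the simulated tables.  Any stage can instead read a
# user-supplied file (screen.wells, psi.junctions, struct.pdb, ...).
seed: 1
outdir: tsl2screen_out
stages: [simulate, screen, splicing, psi, struct]

screen:
  cutoff: 20.0    # % displacement positivity cutoff
  alpha: 0.05     # Bonferroni-adjusted significance level

psi:
  t1: 0.4         # |dPSI| threshold for "modified"
  t2: 0.65        # |dPSI| threshold for "strongly affected"
  motif: AGGTAAG
  max_mismatch: 0

struct:
  selection: all_heavy
  loop_mode: com  # loop-closure distance: centre of mass (or c1)

simulate:
  plate:
    n_compounds: 304
    binder_fraction: 0.18
    mean_displacement: 40.0
    cv: 0.05
  junctions:
    n_events: 200
    depth: 200
    rho: 0.01
    dpsi: 0.5
  hairpin:
    n_frames: 1000
    p_triloop: 0.5
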