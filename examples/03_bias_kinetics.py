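"""Kinetic BRET bias analysis: per-timepoint %Emax/pEC50 and the
transduction-index bias trajectory.

Simulates a two-pathway (G-protein and beta-arrestin-2) kinetic plate with
study-like trajectories, fits every timepoint, and prints the DAMGO-
referenced bias with its propagated standard error.  A positive bias means
G-protein engagement exceeds beta-arrestin-2 engagement relative to DAMGO.
"""

from morpharm import bias
from morpharm import synthetic as syn

timepoints = (2.0, 10.0, 20.0, 30.0, 46.0)
cfg = syn.KineticBretConfig(
    seed=3, timepoints_min=timepoints,
    trajectories=syn.default_kinetic_trajectories(timepoints),
    noise_sd=0.002, n_replicates=3,
)
plate, truth = syn.gen_kinetic_bret(cfg)

traj = bias.timecourse_pharmacology(plate)
go = traj[(traj.pathway == "Go") & (traj.compound == "DFNZ")]
print("DFNZ G-protein efficacy over time (% DAMGO):")
for _, row in go.sort_values("timepoint_min").iterrows():
    print(f"  t={row.timepoint_min:4.0f} min   %Emax={row.emax_pct:6.1f}"
          f"   pEC50={row.pec50:.2f}")
decline = bias.efficacy_decline(go.emax_pct.iloc[0], go.emax_pct.iloc[-1])
print(f"efficacy decline over the time course: {decline:.1f} points\n")

table = bias.bias_table(plate)
print("bias (dTI_Go - dTI_barr2) +/- SE_final:")
for compound in ("FNZ", "DFNZ"):
    sub = table[table.compound == compound].sort_values("timepoint_min")
    for _, row in sub.iterrows():
        print(f"  {compound:5s} t={row.timepoint_min:4.0f}  "
              f"bias={row.bias:+.3f} +/- {row.SE_final:.3f}")
print("\nDAMGO's own bias is identically 0; DFNZ's positive values reflect")
print("its G-protein-favouring potency in the generating trajectories.")
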