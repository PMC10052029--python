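"""RMSD drift and per-residue RMSF on a jittering loop trajectory.

Fitting on the rigid scaffold and reporting on the loop isolates the loop's
own motion; the RMSF profile shows the loop residues fluctuating far above
the scaffold, as a flexible loop should.
"""

import numpy as np

import kinetraj as kt

top, open_frame, closed_frame = kt.synth.make_loop_protein(50, (10, 17), seed=1)
rng = np.random.default_rng(0)
path = np.clip(0.3 + 0.15 * rng.standard_normal(200), 0.0, 1.0)
traj = kt.synth.interpolate_trajectory(
    open_frame, closed_frame, path, topology=top, jitter_sigma=0.15, seed=1
)

fit = kt.traj.select(top, "calpha and not resid 10-17")
loop = kt.traj.select(top, "calpha and resid 10-17")
series = kt.stability.rmsd_series(traj, 0, fit, loop)
mean, sd = kt.stability.equilibrated_stats(series)
print(f"loop RMSD over the equilibrated window: {mean:.2f} +/- {sd:.2f} A")

res_ids, fluct = kt.stability.rmsf(traj, kt.traj.select(top, "calpha"), fit)
loop_mask = np.isin(res_ids, np.arange(10, 18))
print(f"mean RMSF, loop residues:     {fluct[loop_mask].mean():.2f} A")
print(f"mean RMSF, scaffold residues: {fluct[~loop_mask].mean():.2f} A")
print("-> the mobile loop fluctuates far above the scaffold baseline")
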