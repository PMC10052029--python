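"""End-to-end comparison of an 'open' and a 'closed' synthetic system.

The closed system's loop dwells folded onto the ligand; the open system's
loop fluctuates away from it.  The full pipeline reports the three signatures
of loop closure: a shorter loop-ligand distance, a quieter loop, and a
loop-to-hinge community connection that only exists when the loop is closed.
"""

import numpy as np

import kinetraj as kt

top, open_frame, closed_frame = kt.synth.make_loop_protein(50, (10, 17), seed=1)
rng = np.random.default_rng(0)
paths = {
    "open": np.clip(0.15 + 0.1 * rng.standard_normal(300), 0.0, 0.5),
    "closed": np.clip(0.99 + 0.01 * rng.standard_normal(300), 0.95, 1.0),
}
selections = {
    "fit": "calpha and not resid 10-17",
    "report": "calpha",
    "loop": "calpha and resid 10-17",
    "hinge": "calpha and resid 26-28",
    "ligand": "ligand",
}
reports = {}
for name, path in paths.items():
    traj = kt.synth.interpolate_trajectory(
        open_frame, closed_frame, path, topology=top, jitter_sigma=0.15,
        seed=1 if name == "open" else 2,
    )
    reports[name] = kt.pipeline.run_pipeline(
        kt.pipeline.RunConfig(trajectory=traj, selections=selections, seed=1)
    )

cmp = kt.pipeline.compare_systems(reports["open"], reports["closed"])
print(f"loop-ligand distance change (closed - open): "
      f"{cmp['delta_loop_ligand_distance']:+.1f} A")
loop_mask = np.isin(cmp["rmsf_residue_ids"], np.arange(10, 18))
print(f"loop RMSF change (closed - open): {cmp['delta_rmsf'][loop_mask].mean():+.2f} A")
for name in ("open", "closed"):
    link = reports[name]["network"]["loop_hinge_link"]
    n_edges = len(reports[name]["network"]["loop_hinge_contact_edges"])
    print(f"{name:6s}: {n_edges} loop-hinge contact edges, community link: {link}")
print("-> closure shortens the distance, damps the loop, and opens a "
      "loop-to-hinge communication pathway")
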