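"""Counterion contrast: bulky hydrophobic vs small ionic counterions.

Runs the synthetic Monte-Carlo aggregation model once per counterion
mode (shortened runs for a quick demonstration) and compares the final
cluster structure, the summed dye-dye distance and the dye-dye RDF peak.
The bulky counterion glues dyes into one large aggregate; the small ion
leaves the dyes dispersed.
"""

import numpy as np

from dyestack import SyntheticConfig, rdf, run_aggregation, summarize_stats, trajectory_stats
from dyestack.synthetic import default_topology

topology = default_topology()

for mode in ("bulky_hydrophobic", "small_ionic"):
    config = SyntheticConfig(seed=1, counterion_mode=mode, n_steps=10000)
    frames = run_aggregation(config)
    stats = trajectory_stats(frames, topology)
    summary = summarize_stats(stats)
    g = rdf(frames, topology, "dye_dye", r_max=40.0, bin_width=1.0, tail=2.0)
    peak_r = g.bin_centers[int(np.argmax(g.g))]

    print(f"\n== {mode} (seed 1, {config.n_steps} sweeps, {len(frames)} frames) ==")
    print(f"  final largest cluster : {summary['final_largest_cluster']:>4d} of 20 molecules")
    print(f"  full aggregate        : {summary['full_aggregate_reached']}"
          + (f" (first at {summary['first_full_aggregate_time_ns']:.1f} ns)"
             if summary["full_aggregate_reached"] else ""))
    print(f"  final sum of rCC      : {summary['final_sum_rcc_A']:>6.0f} A over 45 dye pairs")
    print(f"  dye-dye g(r) peak     : {peak_r:>6.1f} A")

print(
    "\nThe summed center-center distance drops by roughly a factor of three "
    "when all dyes collapse into one counterion-bridged aggregate, and the "
    "dye-dye RDF peak moves from the featureless large-r region down to "
    "nearest-neighbour contact distances."
)
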