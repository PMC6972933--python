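"""Endpoint analysis of the dissected bundle.

Builds the parcel-by-parcel termination matrix, the per-group endpoint
ratio tables (which parcels the bundle projects to, in percent), the
connection-ratio table (which parcel pairs carry the bundle, in percent),
and exports a connectogram table for circular-plot viewers.
"""

from pathlib import Path

from vofdissect import (
    PhantomConfig,
    SelectionCriteria,
    build_connectivity_matrix,
    connection_ratios,
    endpoint_ratios,
    export_connectogram,
    make_phantom,
    run_selection,
)

phantom = make_phantom(PhantomConfig(n_vof=2000, n_ilf=80, n_af=80, n_clutter=50, seed=7))
criteria = SelectionCriteria(
    hemisphere="L",
    lateral_reference=phantom.bundle("ilf"),
    posterior_reference=phantom.bundle("af"),
)
report = run_selection(phantom.tractogram, phantom.parcellation, criteria)
matrix = build_connectivity_matrix(report, phantom.parcellation, "L")

print(f"accepted tracts: {matrix.total()}")

ratios = endpoint_ratios(matrix, phantom.parcellation.table)
for group, series in ratios.items():
    top = series.sort_values(ascending=False).head(3).round(1)
    print(f"\ntop {group} endpoint parcels (% of the group's endpoints):")
    print(top.to_string())

top_pairs = connection_ratios(matrix).sort_values(ascending=False).head(4).round(1)
print("\nstrongest connections (% of all accepted tracts):")
print(top_pairs.to_string())

out = Path("scratch") if Path("scratch").exists() else Path(".")
path = export_connectogram(matrix, phantom.parcellation.table, out / "connectogram.tsv")
print(f"\nconnectogram table written to {path}")
print("Each percentage says how much of the bundle terminates in (or "
      "connects) the named cortical areas; each group column sums to 100.")
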