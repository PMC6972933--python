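"""Virtually dissect the VOF out of a cluttered phantom tractogram.

The selection keeps streamlines that (1) link a dorsal-group parcel with a
ventral- or lateral-occipital-group parcel, (2) course dominantly
superior-inferior ("blue" on an RGB direction map), (3) stay posterior to
the AF reference and lateral to the ILF reference.
"""

from vofdissect import PhantomConfig, SelectionCriteria, make_phantom, run_selection

phantom = make_phantom(PhantomConfig(n_vof=500, n_ilf=80, n_af=80, n_clutter=50, seed=42))

criteria = SelectionCriteria(
    hemisphere="L",
    group_a=("dorsal",),
    group_b=("ventral", "lateral_occipital"),
    lateral_reference=phantom.bundle("ilf"),
    posterior_reference=phantom.bundle("af"),
)
report = run_selection(phantom.tractogram, phantom.parcellation, criteria)

print(f"input streamlines : {report.n_input}")
print(f"accepted as VOF   : {len(report.accepted)}")
for stage, n in report.rejections.items():
    print(f"rejected by {stage:11s}: {n}")

truth = set(phantom.bundle_indices("vof"))
accepted = set(report.accepted)
recall = len(accepted & truth) / len(truth)
precision = len(accepted & truth) / len(accepted)
print(f"\nrecall vs generator truth    : {recall:.3f}")
print(f"precision vs generator truth : {precision:.3f}")
print("\nOn a well-separated phantom the dissection recovers the true "
      "bundle exactly; the rejection counts show which filter caught "
      "each non-VOF streamline.")
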