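"""Run the full single-image analysis chain on a simulated field of view
and compare the recovered quantities with the planted ground truth."""

from nanofa import CellShapeParams, PlantedFA, SceneSpec, analyse_image, render_scene

scene = SceneSpec(
    image_shape=(512, 512),
    cell_shape=CellShapeParams(base_radius=220, perturb_amplitudes=(0.05, 0.03), seed=3),
    fa_list=(
        PlantedFA(centre=(256, 256), major_axis=30, minor_axis=10),   # keeps
        PlantedFA(centre=(180, 200), major_axis=40, minor_axis=12,
                  orientation=0.7),                                   # keeps
        PlantedFA(centre=(330, 300), major_axis=12, minor_axis=10),   # too round
        PlantedFA(centre=(200, 330), major_axis=6, minor_axis=3),     # too small
    ),
    seed=3,
)
record, truth = render_scene(scene)
result = analyse_image(record, image_name="demo")

print("stage counts:", result["counts"])
print("\nper-cell morphometrics:")
print(result["cells"][
    ["area_um2", "perimeter_um", "circularity", "roundness", "aspect_ratio", "n_fa"]
].round(3).to_string(index=False))
print(f"(planted cell area: {truth.cell_area_um2:.1f} um^2)")

print("\naccepted focal adhesions:")
print(result["fas"][
    ["fa_id", "area_um2", "aspect_ratio", "d_um", "d_norm_maxr", "d_norm_area"]
].round(3).to_string(index=False))
print("(planted edge distances:",
      truth.fa_table.true_edge_distance_um.round(3).tolist(), "um)")
# Of the four planted adhesions only two pass the shape filters
# (1.5 < AR < 8.5, area >= 0.05 um^2); their recovered edge distances d_um
# match the planted values to within one 34 nm pixel.
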