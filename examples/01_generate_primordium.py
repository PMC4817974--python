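"""Generate a synthetic intestinal primordium and inspect its ground truth.

Builds the 20-cell post-hatching tube (4-cell int1, hexagonal RaL packing
posteriorly, the invariant RaL+LaR pair between int2 and int1), prints the
cell inventory and per-cell volumes, and voxelizes it into a confocal-style
label stack (49 Z-slices at 0.5 um, as in the reference acquisition).
"""

from gutmorph import PackingSpec, generate_tube, hatching_configs, voxelize

spec = PackingSpec(cells_per_ring={1: 4})  # 9 rings, int1 divided -> 20 cells
frame = generate_tube(spec, configs=hatching_configs(spec))

print(f"cells: {len(frame.cells)} "
      f"(ring 1 holds {len(frame.ring(1))}: the int1 daughters)")
print(f"tube circumference: {spec.circumference} um, radius {spec.radius:.2f} um")
print("\nper-cell volumes (um^3, analytic ground truth vs mesh):")
for cell in frame.cells[:6]:
    truth = frame.meta["volumes"][str(cell.owner)]
    print(f"  {str(cell.owner):4s}  {truth:7.1f}  {cell.volume:7.1f}")
print("  ...")

stack, label_map = voxelize(frame)
print(f"\nlabel stack: {stack.shape} voxels (Z x Y x X), "
      f"{stack.voxel_xy} um xy pixels, {stack.z_step} um z step")
print(f"labelled voxels: {(stack.data > 0).sum()} across "
      f"{len(stack.labels())} cells")
# Each mesh is watertight and the voxel volume agrees with the analytic
# ground truth to a few percent - the stack is a faithful stand-in for a
# hand-traced segmentation with known answers.
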