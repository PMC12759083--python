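"""Mask-based per-mitochondrion quantification and "R over background".

Simulates a noiseless image of curvilinear mitochondria-like objects, half
with membrane potential (dye-positive), partitions them with the published
mask algebra, and measures per-object PINK1 intensity and channel
colocalisation against a pixel-randomised null.
"""

from mitosense import image_quant as iq
from mitosense import synthetic_data as sd

cfg = sd.ImageSimConfig(shape=(256, 256), n_mito=20, frac_low_mmp=0.5,
                        noise_sd=0.0, seed=4)
channels, truth = sd.simulate_cell_image(cfg)
cell_roi = [(2, 2), (2, 253), (253, 253), (253, 2)]

masks = iq.make_masks(channels, cell_roi, threshold=(80, 255))
print(f"objects planted: {len(truth.entities)} "
      f"({(truth.entities['mmp_class'] == 'low_mmp').sum()} depolarised)")
print(f"mito mask: {int(masks.mito_mask.sum())} px; "
      f"dye-negative partition: {int(masks.partition_a.sum())} px")

table = iq.roi_intensities(channels, masks)
by_part = table.groupby("partition")[["area_px", "mean_PINK1"]].agg(
    {"area_px": "sum", "mean_PINK1": "mean"})
print("\nper-partition summary (partition_a = mito minus dye mask):")
print(by_part.round(1))
# PINK1 was rendered 3x brighter on depolarised objects, and exactly that
# contrast reappears between the dye-negative and dye-positive partitions.

res = iq.coloc_r_over_background(channels["PINK1"], channels["MTS"],
                                 cell_roi, n_rand=20, seed=11)
print(f"\nPINK1 vs MTS: r_obs={res.r_obs:.3f}, "
      f"r_rand_mean={res.r_rand_mean:.3f}, "
      f"R over background={res.r_over_background:.3f}")
# PINK1 signal sits on mitochondria (MTS marks all of them), so the
# observed r is high while block-randomised controls hover near zero.
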