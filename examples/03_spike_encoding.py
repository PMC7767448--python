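"""Threshold-based (TBR) spike encoding of one ERP sample.

Each channel's 1 ms amplitude changes become ternary events: +1 when the
rise exceeds theta, -1 when the fall does.  Theta is 1.5 x the standard
deviation of first differences pooled over the sample, so channels with
larger dynamics emit more spikes.
"""
import numpy as np

from erpsnn import CohortSpec, EncoderConfig, encode_sample, generate_cohort, load_montage

montage = load_montage()
samples, _ = generate_cohort(
    CohortSpec(n_per_group=1, time_points=("T1",), seed=2), montage)
sample = next(s for s in samples if s.stimulus == "target")

spikes = encode_sample(sample, EncoderConfig())
counts = spikes.counts()
density = np.abs(spikes.spikes).mean()
print(f"spike matrix: {spikes.spikes.shape}, overall density {density:.1%}")
print(f"positive/negative events: {(spikes.spikes == 1).sum()} / "
      f"{(spikes.spikes == -1).sum()}")

print("mean spikes per channel by site (target stimulus):")
for site in ("frontal", "frontocentral", "temporal", "centroparietal",
             "occipitoparietal"):
    idx = [i for i, c in enumerate(montage.channels)
           if montage.regions.loc[c, "site"] == site]
    print(f"  {site:16s} {counts[idx].mean():6.1f}")
# The posterior-maximal target positivity shows up as higher
# occipitoparietal spike counts -- amplitude topography becomes
# spike-density topography.
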