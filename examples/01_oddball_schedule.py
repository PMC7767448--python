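"""Generate a randomised auditory-oddball stimulus schedule.

Two blocks of 144 stimuli: 62.5% standard tones with rare noise bursts,
targets and distractors at 12.5% each, separated by a jittered
inter-stimulus interval of 1100 +/- 100 ms.
"""
import numpy as np

from erpsnn import generate_schedule

schedule = generate_schedule(seed=7)
counts = schedule.counts()
gaps = np.diff(schedule.onsets())

print(f"events: {len(schedule)} in {schedule.block_count} blocks")
for kind in ("standard", "noise", "target", "distractor"):
    print(f"  {kind:10s} {counts[kind]:4d}  ({100 * counts[kind] / len(schedule):.1f}%)")
print(f"inter-stimulus interval: {gaps.min():.0f}-{gaps.max():.0f} ms "
      f"(mean {gaps.mean():.0f})")
print(f"task duration: {schedule.onsets()[-1] / 60000:.1f} min")
# The composition is exact by construction; only order and timing are random.
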