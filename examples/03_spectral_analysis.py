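"""Slow-wave band power before and after stimulation.

Simulates a stimulation night, selects artifact-free segments in the pre-
and post-stimulation windows, and computes per-region absolute and relative
(percent-increase) slow-wave (0.5-1 Hz) band power.
"""

from sleeptes import (
    HypnogramModel,
    StageSignalModel,
    build_schedule,
    default_region_map,
    detect_stable_n2,
    mark_clean_segments,
    region_band_power,
    relative_band_power,
    simulate_hypnogram,
    simulate_recording,
    spectral_windows,
)
from sleeptes.synthetic import DEFAULT_MONTAGE


def main() -> None:
    hyp = simulate_hypnogram(HypnogramModel(), n_epochs=960, seed=12)
    onset_s = detect_stable_n2(hyp) * hyp.epoch_s
    schedule = build_schedule(onset_s, "stim")
    rec = simulate_recording(hyp, StageSignalModel(), montage=DEFAULT_MONTAGE,
                             schedule=schedule, seed=12)

    windows = spectral_windows(schedule)
    pre_seg = mark_clean_segments(rec, [windows.pre_stim], threshold_uv=300.0)
    post_seg = mark_clean_segments(rec, windows.immediate, threshold_uv=300.0)
    print(f"clean segments: pre {pre_seg.total_s:.0f} s in {len(pre_seg)} "
          f"pieces; post {post_seg.total_s:.0f} s in {len(post_seg)} pieces")

    region_map = default_region_map()
    pre = region_band_power(rec, region_map, pre_seg)
    post = region_band_power(rec, region_map, post_seg)
    rel = relative_band_power(pre, post)

    print(f"{'region':26s} {'pre':>10s} {'post':>10s} {'change %':>9s}")
    for region in pre:
        print(f"{region:26s} {pre[region]:10.1f} {post[region]:10.1f} "
              f"{rel[region]:9.1f}")


if __name__ == "__main__":
    main()
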