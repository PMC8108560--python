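"""Stimulation-protocol bookkeeping on a hypnogram.

Shows the stable-N2 trigger, the 5-block/4-rest schedule (with a pause),
the stimulation-epoch exclusion mask, and the immediate and spectral
analysis windows derived from the schedule.
"""

from sleeptes import (
    HypnogramModel,
    build_schedule,
    detect_stable_n2,
    immediate_window,
    simulate_hypnogram,
    spectral_windows,
    stimulation_epoch_mask,
)


def main() -> None:
    hyp = simulate_hypnogram(HypnogramModel(), n_epochs=960, seed=3)
    onset_epoch = detect_stable_n2(hyp)
    onset_s = onset_epoch * hyp.epoch_s
    print(f"stable N2 (8 consecutive epochs) reached at epoch {onset_epoch} "
          f"-> stimulation onset {onset_s:.0f} s")

    # a 120-s pause inside block 2 shifts the rest of the protocol
    pause = (onset_s + 400.0, onset_s + 520.0)
    schedule = build_schedule(onset_s, "stim", pauses=[pause])
    print(f"blocks: {schedule.block_intervals()}")
    print(f"stimulated time conserved: {schedule.stimulated_s:.0f} s")

    excluded = stimulation_epoch_mask(schedule, hyp.n_epochs)
    print(f"{len(excluded)} epochs overlap stimulation blocks and are "
          f"excluded from all duration statistics")

    imm = immediate_window(schedule)
    print(f"immediate window: {len(imm.immediate)} intervals kept, "
          f"{len(imm.excluded_intervals)} dropped by the pause rule, "
          f"{imm.total_immediate_s():.0f} s total")

    spec = spectral_windows(schedule)
    post_s = sum(e - s for s, e in spec.immediate)
    print(f"spectral windows: pre-stim {spec.pre_stim}, "
          f"post usable {post_s:.0f} s (20 s trimmed after each block)")


if __name__ == "__main__":
    main()
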