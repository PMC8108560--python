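"""Simulate one synthetic night, write/read it as EDF, and score it.

Walks the first half of the pipeline: hypnogram simulation from the stage
Markov chain, stage-conditioned EEG synthesis, EDF round-trip, and staging
with the rule-based scorer, compared against the generator truth.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from sleeptes import (
    HypnogramModel,
    StageSignalModel,
    evaluate,
    preprocess,
    read_edf,
    rule_based_stager,
    simulate_hypnogram,
    simulate_recording,
    write_edf,
)

MONTAGE = ("C3", "C4", "M1", "M2", "EOGL", "EOGR", "EMG")


def main() -> None:
    # 2 h of 30-s epochs from the default overnight Markov chain
    hyp = simulate_hypnogram(HypnogramModel(), n_epochs=240, seed=7)
    print("stage mix:", {s: hyp.stage_names().count(s) for s in
                         ("W", "N1", "N2", "N3", "REM")})

    rec = simulate_recording(hyp, StageSignalModel(), montage=MONTAGE, seed=7)
    print(f"recording: {rec.n_channels} channels x {rec.n_samples} samples "
          f"at {rec.rate:g} Hz")

    with TemporaryDirectory() as tmp:
        path = Path(tmp) / "night.edf"
        write_edf(rec, path)
        back = read_edf(path)
        print(f"EDF round-trip: {path.stat().st_size / 1e6:.1f} MB, "
              f"{back.data.shape} samples back")

        scored = rule_based_stager(preprocess(back))
        metrics = evaluate(scored, hyp)
        print(f"rule-based staging vs truth: accuracy {metrics.accuracy:.3f}, "
              f"kappa {metrics.kappa:.3f}")


if __name__ == "__main__":
    main()
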