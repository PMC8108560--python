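"""Reproduce the published-table statistics and run a small synthetic study.

The first half reruns every statistic computable from the per-subject
summary tables shipped with the package; the second half simulates a
5-subject two-night study end to end and prints its paired contrasts.
"""

from sleeptes.pipeline import StudyConfig, run_study, table_statistics

MONTAGE = ("C3", "C4", "M1", "M2", "EOGL", "EOGR", "EMG")


def main() -> None:
    print("== statistics recomputed from the shipped summary tables ==")
    st = table_statistics()
    for key in ("n3_minutes", "n3_percent", "immediate_n3_s", "immediate_n2_s"):
        r = st[key]
        print(f"{key:15s} F({r.df[0]},{r.df[1]}) = {r.F:5.2f} "
              f"(p = {r.p_anova:.3f});  T = {r.T:4.1f} "
              f"(p = {r.p_wilcoxon:.3f}, {r.alternative})")

    print("\n== synthetic 5-subject study, rule-based staging ==")
    cfg = StudyConfig(n_subjects=5, montage=MONTAGE, stager="rule",
                      include_spectral=False, seed=0)
    results = run_study(cfg)
    for name, r in results["stats"].items():
        print(f"{name:10s} mean diff = {r.mean_diff:6.2f}  "
              f"F = {r.F:5.2f} (p = {r.p_anova:.3f})  "
              f"T = {r.T:4.1f} (p = {r.p_wilcoxon:.3f})")


if __name__ == "__main__":
    main()
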