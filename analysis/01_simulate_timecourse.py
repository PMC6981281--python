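"""Generate the study-condition active-necrosis time course.

Draws 30 Poisson microscopy fields per age at 1, 3, 6, 12 and 18 months
(31, 92, 184, 368, 552 days) around the cycle-model curve with the fitted
parameter set (n0 = 30.3 cells/field, r = 0.141/cycle, period = onset =
31 days), and writes the long-format count table the fitting stage reads.
"""

from pathlib import Path

from necrokinetics import DeathModelParams, NoiseSpec, generate_necrosis_counts
from necrokinetics.io import write_manifest, write_timecourse

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1
TIMES = [31.0, 92.0, 184.0, 368.0, 552.0]
PARAMS = DeathModelParams(n0=30.3, r=0.141, period_days=31.0, onset_days=31.0)
N_FIELDS = 30


def main() -> None:
    tc = generate_necrosis_counts(
        PARAMS, TIMES, N_FIELDS, NoiseSpec(family="poisson"), seed=SEED
    )
    RESULTS.mkdir(exist_ok=True)
    write_timecourse(tc, RESULTS / "timecourse.csv")
    write_manifest(
        RESULTS / "timecourse.manifest.json",
        seed=SEED, times=TIMES, n_fields=N_FIELDS, noise="poisson",
        n0=PARAMS.n0, r=PARAMS.r, period_days=PARAMS.period_days,
        onset_days=PARAMS.onset_days,
    )
    print(f"wrote {len(tc.records)} field counts -> {RESULTS / 'timecourse.csv'}")
    print("mean count per field by age (days):")
    for t, m in tc.mean_counts().items():
        print(f"  day {t:5.0f}: {m:.3f}")


if __name__ == "__main__":
    main()
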