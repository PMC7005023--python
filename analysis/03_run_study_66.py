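"""Re-run the study with 66 specimens per site (nested draws).

Because specimens are drawn sequentially from each site's community with a
fixed per-site seed, the first 33 specimens of each 66-specimen sample are
exactly the sample analysed by 02_run_study_33.py; this isolates the effect
of doubling the sorting effort. Tables land in results/study66/.
"""

from _common import RESULTS, study_config, study_database, study_profiles
from oligocoi.pipeline import run_study


def main() -> None:
    db = study_database()
    config = study_config(specimens_per_site=66)
    result = run_study(db, config, profiles=study_profiles(db), out_dir=RESULTS / "study66")

    total = sum(r.n_specimens for r in result.reports)
    failed = sum(r.n_failed for r in result.reports)
    print(f"20 sites, {total} specimens: {100 * (total - failed) / total:.1f}% barcoding success")
    agg = result.agreement
    print(f"quality classes vs morphology: identical {agg.identical}, "
          f"genetic higher {agg.genetic_higher}, lower {agg.genetic_lower}")
    print(f"tables written to {RESULTS / 'study66'}")


if __name__ == "__main__":
    main()
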