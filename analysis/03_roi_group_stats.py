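#!/usr/bin/env python
"""ROI-level group inference.

Pooled-variance t-tests with Cohen's d for the striatum and its dorsal /
ventral divisions plus the hedonic network, a two-way (group x ROI) ANOVA
over the hedonic network, and Shapiro-Wilk normality checks of the striatal
means.  Writes comparisons.csv and anova.csv under results/run/.
"""

from pathlib import Path

from morpet import io as mio
from morpet.atlas import RegionAtlas
from morpet.cohort import SubjectRecord
from morpet.group_stats import (anova_two_way, hedonic_long_table,
                                region_set_comparisons, shapiro_wilk_check)

OUT = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    atlas = RegionAtlas.from_json(OUT / "atlas.json")
    bpnd = mio.read_bpnd_csv(OUT / "bpnd.csv")
    subjects = mio.read_subjects_csv(OUT / "subjects.csv")
    records = [SubjectRecord(sid, subjects.loc[sid, "group"],
                             bpnd.loc[sid].reindex(atlas.region_names))
               for sid in bpnd.index]

    comps = region_set_comparisons(records, atlas)
    comps.to_csv(OUT / "comparisons.csv", index_label="region_set",
                 float_format="%.10g")
    s = comps.loc["striatum"]
    print(f"striatum: {s.mean_patient:.2f} +/- {s.sem_patient:.2f} vs "
          f"{s.mean_control:.2f} +/- {s.sem_control:.2f}, "
          f"t = {s.t:.2f}, df = {s.df:.0f}, p = {s.p:.3f}, d = {s.cohen_d:.2f}")

    for group in ("patient", "control"):
        striat = bpnd.loc[subjects["group"] == group, atlas.subsets["striatum"]]
        w, p = shapiro_wilk_check(striat.mean(axis=1))
        print(f"Shapiro-Wilk striatal mean, {group}s: W = {w:.3f}, p = {p:.2f}")

    anova = anova_two_way(hedonic_long_table(records, atlas))
    anova.to_frame().to_csv(OUT / "anova.csv", index_label="factor",
                            float_format="%.10g")
    for factor in anova.factors:
        print(f"ANOVA {factor}: F({anova.df_num[factor]}, {anova.df_den}) = "
              f"{anova.f_values[factor]:.2f}, p = {anova.p_values[factor]:.3g}")


if __name__ == "__main__":
    main()
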