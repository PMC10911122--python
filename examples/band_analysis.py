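"""Echointensity banding: EI%, NPV and SD per band, with group comparisons.

Computes the subject x band table for the conventional 50-wide bands and
the per-band sham-vs-surgery t-tests. On this synthetic cohort the group
signal is confined to a narrow intensity range, so no band-level NPV
difference reaches significance — banding dilutes the signal. Run:

    python examples/band_analysis.py
"""

from echorange import BANDS50, SynthParams, generate_cohort
from echorange.pipeline import band_group_comparisons

cohort = generate_cohort(SynthParams(seed=3)).cohort

table = band_group_comparisons(cohort, BANDS50, "sham", "surgery")
npv = table[table.variable == "npv"]

print("sham vs surgery comparison of band NPV (mean intensity per band):")
print(f"{'band':>10} {'sham':>8} {'surgery':>8} {'t':>7} {'p':>7}")
for _, row in npv.iterrows():
    band = f"{int(row.band_lo)}-{int(row.band_hi)}"
    if row.n_a >= 2 and row.n_b >= 2:
        print(f"{band:>10} {row.mean_a:8.2f} {row.mean_b:8.2f} "
              f"{row.t:7.2f} {row.p:7.3f}")
    else:
        print(f"{band:>10} {'too few subjects with pixels in band':>35}")
print()
print("p > 0.05 everywhere: the planted group effect lives inside 86-101,")
print("a sliver of any 50-wide band, so band means cannot separate groups.")
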