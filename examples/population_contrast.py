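"""Two heterogeneous digital-patient populations, compared statistically.

Draws a small older/high-lesion-load population and a young/low-load
one, simulates 5-year histories, and compares relapse activity and mean
B-cell levels with the KS and Wilcoxon tests (at this small n the
p-values are illustrative; the shipped presets use n in the hundreds).
Run: python examples/population_contrast.py
"""

from rrmsim.stats import compare_populations
from rrmsim.trial import PopulationSpec, simulate_population

N = 15   # per population; small so the example runs in ~30 s

pop1_spec = PopulationSpec(
    lesion_load_dist={"HIGH": 1.0},
    ocb_dist={"PRESENT": 0.9, "ABSENT": 0.1},
    onset_age_dist={"30-39": 0.5, "40-49": 0.5},
    disease_duration_years=5.0, n_candidates=N)
pop2_spec = PopulationSpec(
    lesion_load_dist={"LOW_MEDIUM": 1.0},
    ocb_dist={"PRESENT": 0.9, "ABSENT": 0.1},
    onset_age_dist={"18-29": 1.0},
    disease_duration_years=5.0, n_candidates=N)

pop1 = simulate_population(pop1_spec, seed=11)
pop2 = simulate_population(pop2_spec, seed=22)

for name, pop in (("population 1 (older, high load)", pop1),
                  ("population 2 (young, low/medium load)", pop2)):
    print(f"{name}: {100 * pop.fraction_with_relapse:.0f}% of {pop.n_simulated} "
          "patients had >= 1 relapse in 5 years")

report = compare_populations(pop1, pop2, ["B", "TH", "IgG"])
for var, row in report["variables"].items():
    print(f"{var:>4}: median {row['median_A']:.1f} vs {row['median_B']:.1f}, "
          f"KS p = {row['ks_p']:.3g}, Wilcoxon p = {row['wilcoxon_p']:.3g}")
print("relapse-count bins (1-2 vs >=3):", report["relapse_hist"])
print("=> the younger population carries larger homeostatic B/TH compartments, "
      "so per-patient mean B cells separate the populations sharply")
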