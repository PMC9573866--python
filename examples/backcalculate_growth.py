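"""Back-calculate standard length at age with its uncertainty.

Uses the biological intercept method: SL at age is linear in otolith
radius, anchored at the regional size at first increment deposition
(5.9 mm for JP sardine).  The Monte Carlo SD quantifies how the 3.8-6.5
mm uncertainty of that initial size propagates; it shrinks to zero at
the age of catch, where the measured length pins the curve.
"""

from otolife import (
    CohortParams,
    back_calculate_sl,
    gen_fish_cohort,
    mc_backcalc_uncertainty,
)

profiles, _ = gen_fish_cohort(CohortParams.for_region("JP", n_fish=1, seed=7))
fish = profiles[0]

result = back_calculate_sl(fish)
sds = mc_backcalc_uncertainty(fish, (3.8, 6.5), n_draws=10_000, seed=7)

print(f"fish {fish.fish_id}: SL at catch {fish.sl_catch_mm:.1f} mm, "
      f"assumed SL at first increment {result.sl_first_mm} mm")
print("\n age (dph)  radius (um)  SL (mm)  MC SD (mm)")
for i in range(0, result.ages_dph.size, 20):
    print(f"  {result.ages_dph[i]:6d} {result.radius_um[i]:12.1f}"
          f" {result.sl_mm[i]:8.1f} {sds[i]:9.3f}")
print(f"  {result.ages_dph[-1]:6d} {result.radius_um[-1]:12.1f}"
      f" {result.sl_mm[-1]:8.1f} {sds[-1]:9.3f}")
print("\nThe SD declines with age because back-calculation interpolates "
      "between the uncertain initial size and the exactly known catch size.")
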