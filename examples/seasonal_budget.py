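"""Seasonal and annual whole-stream metabolism budgets.

Uses the bundled three-reach campaign dataset (clay CL, Chalk CW,
Greensand GN) to rebuild daily benthic budgets from the campaign-mean
day/night fluxes, combine them with the water-column compartment, and take
annual means. All rates in mmol O2 m-2 d-1; positive NEM = net autotrophy.
"""

import streammetab as smb
from streammetab import campaigns

# daily benthic budget straight from hourly day/night fluxes (CW, summer)
s = campaigns.rebuilt_benthic_budget("CW", "summer")
print("Chalk reach, summer (benthic):")
print(f"  ER_b  = {s.er:6.1f}   (|night flux| x 24 h)")
print(f"  GPP_b = {s.gpp:6.1f}   ((day - night flux) x daylight)")
print(f"  NEM_b = {s.nem:6.1f}   (net over 24 h; positive = autotrophic)")

# combined benthic + water-column budgets per site-season
combined = campaigns.combined_summaries()
print("\ncombined (benthic + water) NEM by site and season:")
for season in ("spring", "summer", "autumn", "winter"):
    row = "  ".join(f"{site} {combined[(site, season)].nem:+7.1f}"
                    for site in campaigns.SITES)
    print(f"  {season:7s} {row}")

print("\nannual means (average of the four seasons):")
for site in campaigns.SITES:
    annual = smb.annual_mean(
        [v for (st, _), v in combined.items() if st == site])
    verdict = "net autotrophic" if annual.nem > 0 else "net heterotrophic"
    print(f"  {site}: NEM = {annual.nem:+6.1f}  ({verdict})")

# benthic share of the whole-stream budget, CW summer
b = campaigns.benthic_summaries()[("CW", "summer")]
c = combined[("CW", "summer")]
shares = smb.relative_contribution(b, c)
print(f"\nbenthic share of CW-summer GPP: {shares['gpp']:.0f}%"
      "  (the streambed dominates whole-stream production)")
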