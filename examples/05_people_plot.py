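"""Render a People Plot: the standardized 100-icon exposure infographic.

Red icons are the percent of the population exposed (one icon = one
percent), the red shade darkens with the mean log10 monthly dose, and grey
icons are the unexposed remainder.
"""

from pathlib import Path

from sanipath import PeoplePlotSpec, render_people_plot

for pct, dose, pop in [(80.0, 5.94, "adult"), (54.0, 5.4, "child")]:
    svg = render_people_plot(PeoplePlotSpec(
        percent_exposed=pct, mean_log10_dose=dose, pathway="produce",
        population=pop, neighborhood="demo-town", dose_scale=(0.0, 10.0)))
    out = Path(f"people_produce_{pop}.svg")
    out.write_text(svg)
    n_red = svg.count('class="exposed"')
    print(f"{out}: {n_red} red icons ({pct:.0f}% exposed, "
          f"dose {dose} log10/month)")
# The adult plot shows 80 red icons shaded darker than the child plot's 54,
# because the adult mean monthly dose is higher on the same color scale.
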