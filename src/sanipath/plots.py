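"""Standardized visual outputs: People Plots, behavior pie charts, and
concentration histograms, all emitted as SVG text.

The People Plot is a 10x10 grid of 100 person icons: red icons count the
percent of the population exposed through a pathway (round-half-up), grey
icons the rest, and the red shade darkens linearly with the mean log10
monthly dose on a configured scale.  Pie charts and histograms are drawn
with matplotlib; the underlying proportions/bins are exposed as pure
functions so they can be checked independently of the rendering.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from collections import Counter

import numpy as np

from .config import FrequencyCategoryMap
from .microbiology import ConcentrationEstimate, OBSERVED


class RenderError(ValueError):
    pass


@dataclass(frozen=True)
class PeoplePlotSpec:
    percent_exposed: float
    mean_log10_dose: float | None  # None when nobody is exposed
    pathway: str
    population: str
    neighborhood: str
    dose_scale: tuple[float, float] = (0.0, 10.0)


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


#: Simple person silhouette (head + body) in a 10x14 box.
_PERSON_PATH = ("M5 0 A2.2 2.2 0 1 1 4.99 0 Z "
                "M2 6 Q5 4.6 8 6 L7.4 10.5 L6.6 10.5 L6.6 14 L3.4 14 "
                "L3.4 10.5 L2.6 10.5 Z")
_GREY = "#c0c0c0"
_LIGHT_RED = (255, 200, 200)
_DARK_RED = (139, 0, 0)


def dose_shade(log10_dose: float, scale: tuple[float, float]) -> str:
    """Hex fill color, linearly interpolated on the configured log10 scale."""
    lo, hi = scale
    t = 0.0 if hi <= lo else min(max((log10_dose - lo) / (hi - lo), 0.0), 1.0)
    rgb = tuple(round(a + t * (b - a)) for a, b in zip(_LIGHT_RED, _DARK_RED))
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def render_people_plot(spec: PeoplePlotSpec) -> str:
    """SVG People Plot: exactly 100 icons, red count == round(percent)."""
    if not 0 <= spec.percent_exposed <= 100:
        raise RenderError(
            f"percent_exposed must be in [0, 100], got {spec.percent_exposed}")
    n_red = round_half_up(spec.percent_exposed)
    red_fill = (dose_shade(spec.mean_log10_dose, spec.dose_scale)
                if spec.mean_log10_dose is not None else _GREY)
    cell, pad = 16, 4
    width = 10 * cell + 2 * pad
    height = 10 * cell + 2 * pad + 34
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" viewBox="0 0 {width} {height}">',
        f'<defs><path id="person" d="{_PERSON_PATH}"/></defs>',
    ]
    for k in range(100):
        row, col = divmod(k, 10)
        fill = red_fill if k < n_red else _GREY
        cls = "exposed" if k < n_red else "unexposed"
        x = pad + col * cell
        y = pad + row * cell
        parts.append(f'<use href="#person" x="{x}" y="{y}" fill="{fill}" '
                     f'class="{cls}"/>')
    caption = (f"{spec.pathway} / {spec.population} / {spec.neighborhood}: "
               f"{spec.percent_exposed:.0f}% exposed")
    if spec.mean_log10_dose is not None and n_red > 0:
        caption += (f", mean dose {spec.mean_log10_dose:.2f} "
                    "log10 E. coli/month")
    parts.append(f'<text x="{pad}" y="{height - 18}" font-size="10" '
                 f'font-family="sans-serif">{caption}</text>')
    if 0 < spec.percent_exposed < 0.5:
        parts.append(f'<text x="{pad}" y="{height - 6}" font-size="8" '
                     f'font-family="sans-serif">exposure below 0.5% renders '
                     'no red icons</text>')
    parts.append("</svg>")
    return "\n".join(parts)


# ----------------------------------------------------------------------------
# Behavior pie chart


def pie_fractions(counts: list[float],
                  cat_map: FrequencyCategoryMap) -> list[tuple[str, float]]:
    """(category label, fraction of respondents) per category, in map order.

    ``counts`` are the tabulated monthly counts; each is matched back to its
    category label via the map's encoding.  Fractions sum to 1.
    """
    if not counts:
        raise RenderError("cannot chart an empty frequency tabulation")
    tally = Counter(cat_map.encode(c) for c in counts)
    n = len(counts)
    return [(lab, tally.get(lab, 0) / n) for lab, _ in cat_map.categories]


def render_behavior_pie(counts: list[float], cat_map: FrequencyCategoryMap,
                        title: str = "") -> str:
    fracs = pie_fractions(counts, cat_map)
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    with matplotlib.rc_context({"svg.hashsalt": "sanipath"}):
        fig, ax = plt.subplots(figsize=(4, 4))
        nonzero = [(lab, f) for lab, f in fracs if f > 0]
        ax.pie([f for _, f in nonzero],
               labels=[f"{lab} ({100*f:.0f}%)" for lab, f in nonzero],
               startangle=90, counterclock=False)
        ax.set_title(title)
        buf = io.StringIO()
        fig.savefig(buf, format="svg", metadata={"Date": None})
        plt.close(fig)
    return buf.getvalue()


# ----------------------------------------------------------------------------
# Concentration histogram


def hist_bins(estimates: list[ConcentrationEstimate]
              ) -> tuple[np.ndarray, np.ndarray, int]:
    """Unit-width log10 bins spanning the observed data.

    Returns (bin_edges, counts_per_bin, n_censored).  Censored samples are
    excluded from the bars and reported separately so they can be marked
    distinctly in the rendering.
    """
    if not estimates:
        raise RenderError("cannot chart an empty concentration set")
    obs = [e.log10_concentration for e in estimates if e.censoring == OBSERVED]
    n_cens = len(estimates) - len(obs)
    if not obs:
        return np.array([]), np.array([]), n_cens
    lo = math.floor(min(obs))
    hi = math.ceil(max(obs))
    if hi == lo:
        hi = lo + 1
    edges = np.arange(lo, hi + 1, dtype=float)
    counts, _ = np.histogram(obs, bins=edges)
    return edges, counts, n_cens


def render_concentration_hist(estimates: list[ConcentrationEstimate],
                              title: str = "") -> str:
    edges, counts, n_cens = hist_bins(estimates)
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    with matplotlib.rc_context({"svg.hashsalt": "sanipath"}):
        fig, ax = plt.subplots(figsize=(5, 3.2))
        if edges.size:
            ax.bar(edges[:-1], counts, width=1.0, align="edge",
                   edgecolor="white")
        for e in estimates:
            if e.censoring != OBSERVED:
                ax.axvline(e.log10_concentration, color="crimson",
                           linestyle=":", linewidth=1)
        if n_cens and not edges.size:
            ax.set_title(f"{title} (all {n_cens} samples censored)")
        else:
            ax.set_title(title + (f" ({n_cens} censored)" if n_cens else ""))
        ax.set_xlabel("log10 E. coli concentration")
        ax.set_ylabel("samples")
        buf = io.StringIO()
        fig.savefig(buf, format="svg", metadata={"Date": None})
        plt.close(fig)
    if not edges.size:
        import warnings
        warnings.warn("all concentration estimates are censored; histogram "
                      "shows limit markers only")
    return buf.getvalue()
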