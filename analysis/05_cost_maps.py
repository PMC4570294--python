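#!/usr/bin/env python
"""Cost and energy-lost surfaces over clinically plausible grids.

Tumor cost P_cost = 200 * M * (1+2X) kcal/day over burdens 0-3 kg and
anaerobic ATP fractions 0-1; the energy-lost fraction p_lost over capture
probabilities 0-0.5 and ATP fractions 0-0.5, with the three tracer
studies marked.  CSVs go to results/; contour PNGs (cosmetic) to
scratch/.
"""

from pathlib import Path

import numpy as np

from tumor_energetics import cost_surface_frame, plost_surface_frame

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)

    cost = cost_surface_frame(200.0, np.linspace(0, 3, 31), np.linspace(0, 1, 21))
    cost.to_csv(RESULTS / "cost_map.csv", index=False)
    mean_burden = cost[
        np.isclose(cost.m_cancer_kg, 0.8) & np.isclose(cost.x_anaerobic, 0.25)
    ]
    print(
        f"cost map: {len(cost)} cells, range "
        f"{cost.p_cost_kcal_per_day.min():.0f}-{cost.p_cost_kcal_per_day.max():.0f} kcal/day; "
        f"near the 0.83 kg mean burden (0.8 kg cell) at X=0.25: "
        f"{float(mean_burden.p_cost_kcal_per_day.iloc[0]):.0f} kcal/day"
    )

    plost = plost_surface_frame(np.linspace(0, 0.5, 26), np.linspace(0, 0.5, 26))
    plost.to_csv(RESULTS / "plost_map.csv", index=False)
    print(f"p_lost map: {len(plost)} cells, max {plost.p_lost.max():.3f}")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for frame, row_col, val, fname in [
            (cost, "m_cancer_kg", "p_cost_kcal_per_day", "cost_map.png"),
            (plost, "p_cancer", "p_lost", "plost_map.png"),
        ]:
            pivot = frame.pivot(index=row_col, columns="x_anaerobic", values=val)
            fig, ax = plt.subplots(figsize=(6, 5))
            cs = ax.contourf(pivot.columns, pivot.index, pivot.values, levels=14)
            fig.colorbar(cs, ax=ax, label=val)
            if fname == "plost_map.png":
                for label, pc, x in [("C", 0.44, 0.26), ("D", 0.26, 0.19), ("E", 0.27, 0.04)]:
                    ax.plot(x, pc, "r*")
                    ax.annotate(label, (x, pc), color="red")
            ax.set_xlabel("x_anaerobic")
            ax.set_ylabel(row_col)
            fig.savefig(SCRATCH / fname, dpi=150)
            plt.close(fig)
        print(f"contours rendered to {SCRATCH}/")
    except ImportError:
        print("matplotlib unavailable; skipped contour rendering")


if __name__ == "__main__":
    main()
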