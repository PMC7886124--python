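"""Population-level summaries.

Builds the mean spatio-temporal heatmap, the preferred-frequency
histograms, the population spatial/temporal response curves with the
10%-of-maximum spatial threshold (in cyc/deg), the binned chirp FFT-ratio
statistics, and the ON/OFF/ON-OFF polarity split. Writes
population_report.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from rgctypes import io as rio
from rgctypes import population as pop
from rgctypes import workflow


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--chirp-bin-hz", type=float, default=1.0)
    args = ap.parse_args()

    trains = rio.read_spike_trains(args.out / "spikes.csv", args.out / "epochs.csv")
    analyses = workflow.analyze_population(trains)

    maps = [a.grating_map for a in analyses
            if a.grating_map is not None and a.grating_map.responsive]
    spectra = [a.spectrum for a in analyses
               if a.spectrum is not None and a.responds_to_chirp]
    profiles = [a.profile for a in analyses]

    heat = pop.population_heatmap(maps)
    curves = pop.response_curves(maps)
    bins = pop.chirp_population_bins(spectra, args.chirp_bin_hz)
    props = pop.polarity_proportions(profiles)
    period_hist, freq_hist = pop.preferred_frequency_distributions(maps)

    report = {
        "n_units": len(analyses),
        "n_grating_responsive": len(maps),
        "n_chirp_responsive": len(spectra),
        "heatmap": np.round(heat, 6).tolist(),
        "preferred_period_hist": {f"{k:g}": v for k, v in period_hist.items()},
        "preferred_frequency_hist": {f"{k:g}": v for k, v in freq_hist.items()},
        "spatial_freqs_cpd": np.round(curves.spatial_freqs_cpd, 4).tolist(),
        "spatial_curve": np.round(curves.spatial_curve, 6).tolist(),
        "temporal_curve": np.round(curves.temporal_curve, 6).tolist(),
        "threshold_cpd": None if curves.threshold_cpd is None
        else round(curves.threshold_cpd, 4),
        "chirp_bins": bins,
        "polarity_proportions": props,
    }
    (args.out / "population_report.json").write_text(json.dumps(report, indent=1))

    i, j = np.unravel_index(np.argmax(heat), heat.shape)
    print(f"population heatmap peak at ({maps[0].periods[i]:g} um, "
          f"{maps[0].freqs[j]:g} Hz); spatial 10% threshold at "
          f"{report['threshold_cpd']} cyc/deg")
    print(f"polarity split of flash responders: "
          + ", ".join(f"{k} {100 * v:.0f}%" for k, v in props.items()))
    print(f"wrote {args.out}/population_report.json")


if __name__ == "__main__":
    main()
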