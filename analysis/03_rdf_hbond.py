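#!/usr/bin/env python
"""RDF peaks and hydrogen-bond occupancy for the three study conditions.

Regenerates the three seeded trajectories, computes the radial
distribution function between the Asp440 carboxylate oxygens and the
contact unit's amide nitrogen, locates the peak, and scores the 3.0 A
distance-criterion hydrogen-bond occupancy. The recovered peaks should sit
at the designed modes (2.75, 2.25, 3.25 A) within one 0.05 A bin.

Writes per-condition g(r) profiles and a summary table under results/.
"""

from pathlib import Path

import pandas as pd

from siechit.atoms import select
from siechit.rdf import hbond_occupancy, radial_distribution, rdf_peak
from siechit.synthetic import build_toy_complex, generate_trajectory, study_conditions

ROOT = Path(__file__).resolve().parents[1]
N_FRAMES = 2000
BIN, RMAX, CUTOFF = 0.05, 8.0, 3.0


def main() -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    rows = []
    for name, spec in study_conditions(seed=0).items():
        system = build_toy_complex(spec)
        traj = generate_trajectory(system, spec, N_FRAMES)
        acceptor = select(system, "resid 440 and name OD1 OD2")
        donor = select(
            system, f"resname NAG and resid {spec.contact_unit} and name N2"
        )
        prof = radial_distribution(traj, acceptor, donor, bin_width=BIN, r_max=RMAX)
        peak = rdf_peak(prof)
        hb = hbond_occupancy(traj, donor, acceptor, cutoff=CUTOFF)
        pd.DataFrame({"r": prof.bin_centers, "g": prof.g}).to_csv(
            results / f"rdf_{name}.tsv", sep="\t", index=False, float_format="%.6f"
        )
        rows.append(
            {
                "condition": name,
                "designed_mode_A": spec.contact_distance_mean,
                "rdf_peak_A": peak,
                "hbond_occupancy": hb.occupancy,
                "median_min_distance_A": float(pd.Series(hb.min_distance).median()),
            }
        )
        print(
            f"{name}: designed {spec.contact_distance_mean:.2f} A -> "
            f"peak {peak:.3f} A, occupancy {hb.occupancy:.3f}"
        )

    summary = pd.DataFrame(rows)
    out = results / "rdf_hbond_summary.tsv"
    summary.to_csv(out, sep="\t", index=False, float_format="%.4f")
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
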