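#!/usr/bin/env python
"""Calibrate the default suspended ring masses.

Inverts the Laplace mass-to-pressure equivalence p = m g / (b r_v) for n
equally spaced target equivalent blood pressures, printing the masses that
belong in the default study configuration:

    python scripts/calibrate_masses.py --p-min 77.2 --p-max 157.4
"""

from __future__ import annotations

import argparse

from aortavisc.synthetic_data import GeometryConfig, calibrate_ring_masses
from aortavisc.viscoelasticity import mass_to_equivalent_pressure


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--p-min", type=float, default=77.2, help="mmHg")
    ap.add_argument("--p-max", type=float, default=157.4, help="mmHg")
    ap.add_argument("--n", type=int, default=4)
    ap.add_argument("--width", type=float, default=0.003,
                    help="strip width b, m")
    ap.add_argument("--radius", type=float, default=0.0013,
                    help="vessel radius r_v, m")
    args = ap.parse_args()

    geometry = GeometryConfig(b=args.width, r_v=args.radius).to_geometry()
    masses = calibrate_ring_masses(geometry, args.p_min, args.p_max, args.n)
    print("ring masses (kg) and the pressures they map back to (mmHg):")
    for m in masses:
        m_rounded = float(f"{m:.6g}")
        p = mass_to_equivalent_pressure(m_rounded, geometry)
        print(f"  {m_rounded:.6g}  ->  {p:.4f}")


if __name__ == "__main__":
    main()
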