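"""Calibrate the six shipped substage presets and freeze them to YAML.

Run from the repository root:

    python scripts/calibrate_defaults.py [--n-cal 12] [--seed 7000]

For each substage this tunes the physical generator parameters
(ellipsoid scale, chromatin coupling, COM displacement) until the mean
measured volume / Pearson r / COM offset over a calibration population
match the reference group means, then writes the frozen presets to
``src/repli3d/presets/default_presets.yaml`` and a calibration report
to ``scratch/calibration_report.json``.  This is a development-time
tool: the shipped YAML is the frozen result.
"""

import argparse
import json
import time
from pathlib import Path

from repli3d.presets import REFERENCE_GROUPS, save_presets, structural_preset
from repli3d.synthetic_nuclei import calibrate_preset


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-cal", type=int, default=12)
    ap.add_argument("--seed", type=int, default=7000)
    ap.add_argument("--out", default="src/repli3d/presets/default_presets.yaml")
    args = ap.parse_args()

    presets = {}
    reports = {}
    for i, (stage, ref) in enumerate(REFERENCE_GROUPS.items()):
        t0 = time.time()
        base = structural_preset(stage)
        preset, report = calibrate_preset(
            base,
            target_volume_um3=ref["volume"][0],
            target_r=ref["r"][0] if ref["r"] else None,
            target_com_offset_um=ref["com"][0] if ref["com"] else None,
            n_cal=args.n_cal,
            seed=args.seed + 100 * i,
        )
        presets[stage] = preset
        reports[stage] = report
        print(
            f"{stage}: vf={preset.volume_factor:.4f} coupling={preset.coupling:.4f} "
            f"d={preset.com_displacement_um:.4f} final={report['final']} "
            f"({time.time() - t0:.0f}s)",
            flush=True,
        )

    save_presets(presets, args.out)
    Path("scratch").mkdir(exist_ok=True)
    Path("scratch/calibration_report.json").write_text(json.dumps(reports, indent=1))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
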