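"""Plain-text I/O: primer/stock configs, manifests and level tables.

Configs are YAML::

    primers:
      P: {forward: GTGCCAGC..., reverse: GGACTACH..., target: 253, window: [252, 254]}
    stocks:
      P: {copies_per_ng: 3.7e8, construct_length_bp: 2504}

Manifests and level tables are TSV with one row per (sample, family) and
per (level, family) respectively.
"""

from __future__ import annotations

from typing import Dict, Tuple

import pandas as pd
import yaml

from .copy_number import SpikeStock
from .spike_design import PrimerPair

MANIFEST_COLUMNS = [
    "sample",
    "family",
    "group",
    "spike_copies",
    "amount",
    "unit",
    "spike_timing",
    "contaminated",
]


def load_config(path) -> Tuple[Dict[str, PrimerPair], Dict[str, SpikeStock]]:
    """Read primer pairs and spike stocks from a YAML config."""
    with open(str(path)) as fh:
        cfg = yaml.safe_load(fh)
    primers = {}
    for name, spec in (cfg.get("primers") or {}).items():
        primers[name] = PrimerPair(
            name,
            spec["forward"],
            spec["reverse"],
            int(spec["target"]),
            (int(spec["window"][0]), int(spec["window"][1])),
        )
    stocks = {}
    for name, spec in (cfg.get("stocks") or {}).items():
        stocks[name] = SpikeStock(
            name,
            float(spec["copies_per_ng"]),
            spec.get("construct_length_bp"),
        )
    return primers, stocks


def dump_config(
    primers: Dict[str, PrimerPair], stocks: Dict[str, SpikeStock], path
) -> None:
    cfg = {
        "primers": {
            n: {
                "forward": p.forward,
                "reverse": p.reverse,
                "target": p.amplicon_length_target,
                "window": list(p.amplicon_length_window),
            }
            for n, p in primers.items()
        },
        "stocks": {
            n: {
                "copies_per_ng": s.copies_per_ng,
                **(
                    {"construct_length_bp": s.construct_length_bp}
                    if s.construct_length_bp
                    else {}
                ),
            }
            for n, s in stocks.items()
        },
    }
    with open(str(path), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def read_manifest(path) -> pd.DataFrame:
    man = pd.read_csv(path, sep="\t")
    missing = {"sample", "family", "spike_copies"} - set(man.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if "contaminated" in man.columns:
        man["contaminated"] = man["contaminated"].astype(bool)
    return man


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_level_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"level", "family", "mass_pg", "copies"} - set(df.columns)
    if missing:
        raise ValueError(f"level table missing columns: {sorted(missing)}")
    return df


def write_level_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
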