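#!/usr/bin/env python
"""Simulate one survey year: 5 soil samples/season (50 g each), 5 pooled
earthworm and earwig samples/taxon/season, 5 procedural blanks/season.

Writes particles.csv, soil_samples.csv, fauna_samples.csv, blanks.csv.
"""

import argparse
from pathlib import Path

from soilmp.data_model import (
    write_blanks,
    write_fauna_samples,
    write_particle_table,
    write_soil_samples,
)
from soilmp.synthetic import default_config, generate_year

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

config = default_config(seed=args.seed)
dataset = generate_year(config)
args.out.mkdir(parents=True, exist_ok=True)
write_particle_table(dataset.particles, args.out / "particles.csv")
write_soil_samples(dataset.soil, args.out / "soil_samples.csv")
write_fauna_samples(dataset.fauna, args.out / "fauna_samples.csv")
write_blanks(dataset.blanks, args.out / "blanks.csv")
config.to_yaml(args.out / "generator_config.yaml")

print(f"seed={args.seed}: {len(dataset.particles)} particles "
      f"({sum(p.confirmed for p in dataset.particles)} polymer-confirmed), "
      f"{len(dataset.soil)} soil samples, {len(dataset.fauna)} pooled fauna "
      f"samples, {len(dataset.blanks)} blanks -> {args.out}/")
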