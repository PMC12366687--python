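"""Tab-separated text I/O for event, ground-truth and particle tables."""

from __future__ import annotations

import pandas as pd

from .localize import LocalizedFluorophore, ParticleProjection
from .simulate import EVENT_COLUMNS, TRUTH_COLUMNS

PARTICLE_COLUMNS = ["particle_id"] + [
    f"{name}_{i}"
    for i in range(3)
    for name in ("x_nm", "y_nm", "sigma_x", "sigma_y", "n_loc", "precision_nm")
]


def write_events(events: pd.DataFrame, path) -> None:
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return df


def write_truth(truth: pd.DataFrame, path) -> None:
    truth[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_particles(particles, path) -> None:
    rows = []
    for p in particles:
        row = {"particle_id": p.particle_id}
        for i, f in enumerate(p.fluorophores):
            row.update(
                {
                    f"x_nm_{i}": f.x,
                    f"y_nm_{i}": f.y,
                    f"sigma_x_{i}": f.sigma_x,
                    f"sigma_y_{i}": f.sigma_y,
                    f"n_loc_{i}": f.n_loc,
                    f"precision_nm_{i}": f.precision,
                }
            )
        rows.append(row)
    pd.DataFrame(rows, columns=PARTICLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_particles(path):
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        fluors = tuple(
            LocalizedFluorophore(
                x=row[f"x_nm_{i}"],
                y=row[f"y_nm_{i}"],
                sigma_x=row[f"sigma_x_{i}"],
                sigma_y=row[f"sigma_y_{i}"],
                n_loc=int(row[f"n_loc_{i}"]),
                precision=row[f"precision_nm_{i}"],
            )
            for i in range(3)
        )
        out.append(ParticleProjection(particle_id=int(row["particle_id"]), fluorophores=fluors))
    return out
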