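"""Generate the synthetic ICU study dataset.

Writes patients.csv / hct.csv / fluids.csv plus ground_truth.csv (the
latent leak fraction per patient) under results/data/. The defaults
emulate a large North-American-style ICU extract: ~5000 stays, left-skewed
leak index, ~15% hospital mortality.
"""

from pathlib import Path

from vli.synthetic_data import SimulationConfig, write_synthetic_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
N_PATIENTS = 5000
SEED = 1


def main() -> None:
    cfg = SimulationConfig(n_patients=N_PATIENTS, seed=SEED)
    paths = write_synthetic_dataset(cfg, OUT)
    print(f"simulated {N_PATIENTS} ICU stays (seed {SEED})")
    for name, p in paths.items():
        print(f"  {name}: {p}")


if __name__ == "__main__":
    main()
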