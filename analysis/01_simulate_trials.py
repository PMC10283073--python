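"""Generate the synthetic irradiation study.

Replicates the published power-bin designs for 1-s and 60-s irradiation at
10x the per-bin trial counts (the published counts are kept as-is in the
design object; the inflation buys stable curve fits downstream), draws
outcomes from the default true endpoint curves, and writes the trial tables
plus truth sidecars under results/.

Run from the repository root:  python analysis/01_simulate_trials.py
"""

from pathlib import Path

from irdose import default_truth, replicate_design, simulate_trials, write_trials

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20230605
INFLATE = 10

RESULTS.mkdir(exist_ok=True)
for duration in (60, 1):
    design = replicate_design(duration).inflate(INFLATE)
    # the study's conditions include the cell-size effect (smaller cells
    # respond at lower power); the size-free variant is the c = 0 section
    truth = default_truth(duration, size_effect=True)
    ds = simulate_trials(design, truth, seed=SEED + duration)
    out = RESULTS / f"trials_{duration}s.csv"
    write_trials(ds, out)
    truth.to_json(RESULTS / f"truth_{duration}s.json")
    frame = ds.to_frame()
    print(f"{duration:>2d} s design: {len(ds)} trials -> {out.name}")
    print(
        "    endpoint frequencies: "
        + ", ".join(f"{ep}={frame[ep].mean():.3f}" for ep in ("target", "neighboring", "local", "death"))
    )
    print(f"    mean cell size {frame['cell_size_um2'].mean():,.0f} um^2")
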