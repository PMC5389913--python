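"""The end-to-end workflow on structure files.

Writes a small synthetic benchmark to PDB files (with a truth manifest and
planted annotations), runs the full pipeline -- parsing, site extraction,
two-round detection, classification, compressed labeling, clustering --
and prints the per-metal summary.  Equivalent shell command:

    metalcg run-all BENCH_DIR -o RUN_DIR --metals Zn,Fe --seed 5 \
        --annotations BENCH_DIR/annotations.tsv
"""

import json
import tempfile
from pathlib import Path

from metalcg import SyntheticSpec, write_benchmark
from metalcg.pipeline import PipelineConfig, run

workdir = Path(tempfile.mkdtemp(prefix="metalcg_example_"))
bench = write_benchmark(
    [
        SyntheticSpec(metal="Zn", cg_code="Tet", n_sites=30,
                      decoys_per_site=1, seed=11),
        SyntheticSpec(metal="Fe", cg_code="Oct", n_sites=30,
                      misassign_fraction=0.1, seed=12),
    ],
    workdir / "bench",
    plant_annotations=True,
)
print(f"benchmark written to {bench} ({len(list(bench.glob('*.pdb')))} PDB files)")

config = PipelineConfig(metals=("Zn", "Fe"), seed=5,
                        annotations=str(bench / "annotations.tsv"))
run_dir = run(config, bench, workdir / "run")
summary = json.loads((run_dir / "report.json").read_text())
for metal in ("Zn", "Fe"):
    info = summary[metal]
    print(f"\n{metal}: {info['n_detected']}/{info['n_input_sites']} sites survive"
          f" detection; excluded: {info['excluded'] or 'none'}")
    print(f"  recalibrated cutoff {info['updated_upper']:.3f} A, "
          f"whitelist {info['whitelist']}")
    print(f"  coordination counts {info['coordination_counts']}, "
          f"error rate {info['error_rate']:.6f}")
    print(f"  chosen k = {info['clustering'].get('k')}")
print(f"\nstage artifacts (TSV/JSON) are under {run_dir}")
print(
    "The misassigned Fe sites are removed by the average-deviation filter,"
    " and the per-metal error rate estimates how often detection keeps a"
    " ligand it should not."
)
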