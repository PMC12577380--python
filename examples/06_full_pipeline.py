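"""Run every stage end to end from one configuration and inspect the
reproducible output bundle."""

import json
from pathlib import Path

from cprkit.pipeline import PipelineConfig, run_all
from cprkit.synthetic import SynthConfig

out_dir = Path("scratch/example_bundle")
config = PipelineConfig(
    output_dir=str(out_dir),
    seed=42,
    simulate=SynthConfig(seed=42, n_experiments=2, planted_pairs=1),
)
written = run_all(config)
print(f"wrote {len(written)} outputs:")
for name in sorted(written):
    print(" ", written[name].name)

manifest = json.loads((out_dir / "manifest.json").read_text())
print("\nconfig hash:", manifest["config_sha256"][:16], "... seed:", manifest["seed"])
print("Re-running with the same configuration reproduces every file byte for byte;")
print("the manifest's checksums make that verifiable.")
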