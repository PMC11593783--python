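"""Whole-study pipeline on simulated mitogenomes.

Simulates an annotated 13-gene mitogenome set with degenerate second
control regions (GO-IV), writes it to GenBank, reads it back, and runs
every analysis stage, printing the bundle of artifacts a comparative
mitogenomics paper would tabulate.
"""

import tempfile
from pathlib import Path

import mitobias as mb

cfg = mb.SimConfig(seed=3, n_species=4, go_type="GO-IV", omega=0.15)
data = mb.simulate_dataset(cfg)

workdir = Path(tempfile.mkdtemp(prefix="mitobias_demo_"))
gb = workdir / "genomes.gb"
mb.write_genbank(data.genomes, gb)
genomes = mb.read_genbank(gb)

run_cfg = mb.RunConfig(outdir=workdir / "bundle")
written = mb.run_all(genomes, run_cfg, source=str(gb))

print("artifacts written:")
for name in sorted(written):
    print(f"  {written[name]}")

cr_table = (workdir / "bundle" / "cr_table.tsv").read_text().splitlines()
print("\ncontrol-region report (first lines):")
for line in cr_table[:3]:
    print("  " + "\t".join(line.split("\t")[:11]))
print("\nEvery species keeps a full CR1; the degraded CR2 loses its "
      "conserved domains and identity, hence the GO-IV calls.")
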