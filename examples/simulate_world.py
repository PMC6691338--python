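"""Generate a reproducible synthetic study and write its input files.

The generator emulates the structure network inference relies on: drugs in
structural clusters share substructure blocks and (with probability
``signal_strength``) targets; an SMG catalog covers 24 cancer types; a
planted drug-cancer pair carries a real enrichment signal.  The same seed
always produces byte-identical files.
"""

import tempfile
from pathlib import Path

from netpharm import SynthConfig, gen_world
from netpharm.catalog_io import write_dti_catalog, write_smg_catalog
from netpharm.substructures import write_matrix

config = SynthConfig(seed=42, planted=("D000", "CAN05", 0.5))
catalog, matrix, smg, truth = gen_world(config)

out = Path(tempfile.mkdtemp())
write_dti_catalog(catalog, out / "dti.tsv", params={"seed": config.seed})
write_matrix(matrix, out / "fp.tsv")
write_smg_catalog(smg, out / "smg.gmt")
truth.to_json(out / "truth.json")

print(f"world seed={config.seed}")
print(f"  interactions : {len(catalog)} ({len(catalog.drugs)} drugs, {len(catalog.targets)} targets)")
print(f"  fingerprints : {matrix.n_drugs} x {matrix.n_substructures} binary matrix")
print(f"  SMG catalog  : {len(smg)} cancer types, {len(smg.all_genes)} distinct genes")
print(f"  planted      : {truth.planted_drug} -> {truth.planted_cancer} "
      f"({len(truth.planted_overlap_genes)} shared genes)")
print(f"  files        : {out}/dti.tsv, fp.tsv, smg.gmt, truth.json")
# truth.json records every planted fact so recovery tests can check that the
# pipeline finds exactly what was hidden.
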