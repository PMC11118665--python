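"""Measure conformational changes in real deposited structure pairs.

Requires network access (or pre-fetched files in data/pdb/): downloads the
five benchmark conformer pairs from RCSB and reports the aligned Cα RMSD
between initial and target under each preset's chain/model conventions —
e.g. T4 lysozyme 172L vs 1L69 should give about 3.95 Å over 162 residues.
"""

from pathlib import Path

from fretrest.presets import PRESETS, load_preset_pair
from fretrest.structures import ca_rmsd

pdb_dir = Path(__file__).resolve().parent.parent / "data" / "pdb"

for name in ("T4L", "PGK", "AK", "GB1", "TCI"):
    preset = PRESETS[name]
    try:
        initial, target = load_preset_pair(name, pdb_dir, download=True)
    except Exception as exc:
        print(f"{name:>4}: unavailable ({type(exc).__name__}: {exc})")
        continue
    rmsd = ca_rmsd(initial, target, align=True)
    print(f"{name:>4}: {preset.initial_id} -> {preset.target_id}  "
          f"N={initial.n_residues:<4} aligned CA RMSD {rmsd:.2f} A")
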