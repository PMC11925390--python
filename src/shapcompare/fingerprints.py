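"""Fingerprinting of real compound tables (optional; requires RDKit).

The analysis itself is representation-agnostic: any binary instance x
feature matrix works. This helper turns a table of SMILES into folded
Morgan/ECFP4-style bit vectors for real-data runs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import FingerprintDataset


def smiles_to_fingerprints(
    smiles: Sequence[str], n_bits: int = 2048, radius: int = 2
) -> np.ndarray:
    """Folded binary Morgan fingerprints (radius 2 = bond diameter 4)."""
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "RDKit is required for fingerprinting; install the 'chem' extra"
        ) from exc
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        rows.append(np.array(gen.GetFingerprint(mol), dtype=np.uint8))
    return np.vstack(rows)


def dataset_from_smiles_table(
    table: pd.DataFrame,
    smiles_col: str = "smiles",
    label_col: str = "label",
    id_col: str = "compound_id",
    n_bits: int = 2048,
) -> FingerprintDataset:
    """Fingerprint a compound table (labels 'active'/'inactive')."""
    bits = smiles_to_fingerprints(table[smiles_col].tolist(), n_bits=n_bits)
    return FingerprintDataset(
        bits=bits,
        labels=(table[label_col] == "active").astype(int).to_numpy(),
        compound_ids=table[id_col].astype(str).tolist(),
    )
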