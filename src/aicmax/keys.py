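"""Substructure key dictionaries for structure-key fingerprints.

The Klekota–Roth fingerprint (KRFP) is a non-hashed structural-key
fingerprint with 4860 bits, each bit tied to one exact SMARTS-defined
fragment. The original SMARTS dictionary is distributed with external
descriptor software and is not redistributed here; this module provides

* :func:`load_smarts_keys` — load any (index, SMARTS) dictionary from a
  plain-text file, e.g. a real KRFP export;
* :func:`synthetic_krfp_keys` — a synthetic stand-in dictionary with the
  same size (4860 keys) and format, for plumbing and scale tests;
* :func:`demo_pharmacophore_keys` — a small curated set of genuine
  pharmacophore fragments (amide, aromatic ring, piperazine, ...) for
  worked examples on real molecules.
"""

from __future__ import annotations

from itertools import product
from pathlib import Path

KRFP_SIZE = 4860
"""Number of bits in the Klekota–Roth structural-key fingerprint."""


def load_smarts_keys(path: str | Path) -> list[tuple[int, str]]:
    """Load an ordered (bit index, SMARTS) dictionary from text.

    Accepted line formats: ``SMARTS`` alone (bit index = line number,
    0-based) or ``index<whitespace>SMARTS``. Blank lines and ``#``
    comments are skipped.
    """
    keys: list[tuple[int, str]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) == 2 and parts[0].isdigit():
                keys.append((int(parts[0]), parts[1]))
            else:
                keys.append((len(keys), line))
    return keys


def synthetic_krfp_keys(n_keys: int = KRFP_SIZE) -> list[tuple[int, str]]:
    """Synthetic stand-in for the KRFP SMARTS dictionary.

    Generates ``n_keys`` distinct, syntactically valid SMARTS patterns
    (linear four-atom fragments over common organic atoms) in a fixed
    deterministic order. This is NOT the published Klekota–Roth key set —
    it reproduces only its size and (index, SMARTS) format so that
    pipelines can be exercised end-to-end without the proprietary
    resource file.
    """
    atoms = ("C", "N", "O", "S", "P", "c", "n", "o", "Cl")
    patterns = []
    for combo in product(atoms, repeat=4):
        patterns.append("~".join(combo))
        if len(patterns) == n_keys:
            break
    if len(patterns) < n_keys:
        raise ValueError(f"cannot generate {n_keys} keys from the fragment grammar")
    return list(enumerate(patterns))


def demo_pharmacophore_keys() -> list[tuple[int, str]]:
    """A small curated dictionary of real pharmacophore fragments.

    Indices are arbitrary demo ids, not KRFP indices.
    """
    smarts = [
        ("benzene", "c1ccccc1"),
        ("amide", "C(=O)N"),
        ("sulfonamide", "S(=O)(=O)N"),
        ("piperazine", "N1CCNCC1"),
        ("piperidine", "N1CCCCC1"),
        ("methoxy_aryl", "cOC"),
        ("basic_amine", "[NX3;H2,H1;!$(NC=O)]"),
        ("carboxylic_acid", "C(=O)[OH]"),
        ("halogen_on_aryl", "c[F,Cl,Br,I]"),
        ("ether", "[#6]-O-[#6]"),
        ("hydroxyl", "[OX2H]"),
        ("nitrile", "C#N"),
    ]
    return [(i, patt) for i, (_, patt) in enumerate(smarts)]
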