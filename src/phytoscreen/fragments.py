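"""Frequent-fragment profiling.

A fragment dictionary maps names to SMARTS substructure patterns; for a set of
molecules the frequency of a fragment is the fraction of molecules containing
at least one embedding of the pattern (molecules are counted, not
occurrences). The default dictionary ships the ring systems and small
functional fragments most informative for contrasting natural-product-like
actives against synthetic drugs: aromatic N-heterocycles (pyridine,
pyrimidine, imidazole, pyrrole, pyrazole), saturated N/O-heterocycles
(pyrrolidine, piperazine, morpholine, tetrahydropyran, tetrahydrofuran),
carbocycles (benzene, cyclohexane, cyclohexene, cyclopentane), and the
trifluoroethane and methyl-acetate motifs. It is user-extensible via TSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from rdkit import Chem

from .errors import ConfigurationError, StructureError

#: name -> SMARTS. Aromatic/aliphatic atom types keep e.g. benzene distinct
#: from cyclohexane and pyridine distinct from piperidine.
DEFAULT_FRAGMENTS: list[tuple[str, str]] = [
    ("pyridine", "c1ccncc1"),
    ("pyrimidine", "c1cncnc1"),
    ("imidazole", "c1cncn1"),
    ("pyrrole", "c1ccnc1"),
    ("pyrrolidine", "C1CCNC1"),
    ("piperazine", "C1CNCCN1"),
    ("pyrazole", "c1ccnn1"),
    ("trifluoroethane", "CC(F)(F)F"),
    ("morpholine", "C1COCCN1"),
    ("cyclohexane", "C1CCCCC1"),
    ("cyclohexene", "C1=CCCCC1"),
    ("tetrahydropyran", "C1CCOCC1"),
    ("tetrahydrofuran", "C1CCOC1"),
    ("cyclopentane", "C1CCCC1"),
    ("methyl_acetate", "CC(=O)OC"),
    ("benzene", "c1ccccc1"),
]


@dataclass
class FragmentDictionary:
    """Named, pre-compiled substructure queries."""

    entries: list[tuple[str, str]]

    def __post_init__(self):
        names = [n for n, _ in self.entries]
        if len(names) != len(set(names)):
            raise ConfigurationError("duplicate fragment names in dictionary")
        self._queries = {}
        for name, pattern in self.entries:
            q = Chem.MolFromSmarts(pattern)
            if q is None:
                raise ConfigurationError(
                    f"fragment {name!r} has unparseable SMARTS pattern {pattern!r}"
                )
            self._queries[name] = q

    @classmethod
    def default(cls) -> "FragmentDictionary":
        return cls(entries=list(DEFAULT_FRAGMENTS))

    @classmethod
    def from_tsv(cls, path) -> "FragmentDictionary":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("name", "pattern"):
            if col not in df.columns:
                raise ConfigurationError(f"fragment table {path} lacks column {col!r}")
        return cls(entries=list(zip(df["name"], df["pattern"])))

    def query(self, name: str):
        return self._queries[name]

    def names(self) -> list[str]:
        return [n for n, _ in self.entries]


def match_fragment(smiles: str, pattern: str) -> bool:
    """True iff the molecule contains at least one embedding of the pattern."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(smiles)
    q = Chem.MolFromSmarts(pattern)
    if q is None:
        raise ConfigurationError(f"unparseable SMARTS pattern {pattern!r}")
    return mol.HasSubstructMatch(q)


def _set_counts(molecules, dictionary: FragmentDictionary) -> dict[str, int]:
    counts = {name: 0 for name in dictionary.names()}
    for rec in molecules:
        smiles = rec.smiles if hasattr(rec, "smiles") else rec
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise StructureError(smiles)
        for name in dictionary.names():
            if mol.HasSubstructMatch(dictionary.query(name)):
                counts[name] += 1
    return counts


def frequency_table(
    set_a, set_b, dictionary: FragmentDictionary | None = None
) -> pd.DataFrame:
    """Per-fragment presence counts/fractions for two molecule sets.

    Rows are sorted by frequency in set B descending (then fragment name), so
    with B = a drug panel the most drug-typical fragments come first. Rows
    where a fragment is absent from both sets are retained.
    """
    if dictionary is None:
        dictionary = FragmentDictionary.default()
    if not dictionary.entries:
        raise ConfigurationError("empty fragment dictionary")
    if not set_a or not set_b:
        raise ConfigurationError("fragment frequency needs two non-empty sets")
    counts_a = _set_counts(set_a, dictionary)
    counts_b = _set_counts(set_b, dictionary)
    rows = [
        {
            "fragment": name,
            "count_a": counts_a[name],
            "freq_a": counts_a[name] / len(set_a),
            "count_b": counts_b[name],
            "freq_b": counts_b[name] / len(set_b),
        }
        for name in dictionary.names()
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["freq_b", "fragment"], ascending=[False, True], ignore_index=True
    )
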