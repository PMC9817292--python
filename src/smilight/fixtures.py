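"""Built-in SMILES collections used for demos and test fixtures.

``DRUG_SMILES`` is a small curated list of drug-like molecules spanning the
syntax the tokenizer must handle: rings (plain and ``%nn``), nested branches,
bracket atoms with charges, isotopes, chirality and H-counts, aromatics,
directional bonds and disconnected fragments.  ``fixture_smiles`` expands it
combinatorially (scaffold x substituent) to a few hundred distinct valid
strings for property testing.
"""

from __future__ import annotations

DRUG_SMILES: tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O",                      # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",                 # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",                 # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",                         # paracetamol
    "CN1CCC[C@H]1c1cccnc1",                       # nicotine
    "C1CCCCC1",                                   # cyclohexane
    "c1ccccc1",                                   # benzene
    "Brc1c(Br)c(Br)c(Br)c(Br)c1Br",               # hexabromobenzene
    "C(=CCN(CC=C)CC=C)C",                         # triallylamine-like
    "OC(=O)C(Cl)(Cl)Cl",                          # trichloroacetic acid
    "[N+](C)(C)(C)C",                             # tetramethylammonium
    "C[N+](C)(C)CCO",                             # choline
    "[13CH4]",                                    # isotope-labelled methane
    "[2H]OC([2H])([2H])[2H]",                     # deuterated methanol
    "N[C@@H](C)C(=O)O",                           # L-alanine
    "C[C@H](N)C(=O)O",                            # D-alanine written reversed
    "[O-]C(=O)c1ccccc1",                          # benzoate anion
    "C/C=C/C=O",                                  # crotonaldehyde (trans)
    "C/C=C\\C",                                   # cis-butene
    "c1ccc2ccccc2c1",                             # naphthalene
    "C1CC2CCC1CC2",                               # bicyclooctane
    "c1ccc2c(c1)Cc1ccccc1-2",                     # fluorene
    "C%10CCCCC%10",                               # two-digit ring closure
    "[Na+].[Cl-]",                                # salt, dot disconnect
    "CCOC(=O)c1ccc(N)cc1",                        # benzocaine
    "Clc1ccc(cc1)C(c1ccc(Cl)cc1)C(Cl)(Cl)Cl",     # DDT
    "O=[N+]([O-])c1ccc(cc1)N",                    # 4-nitroaniline
    "CSCC[C@H](N)C(=O)O",                         # methionine
    "c1cc[nH]c1",                                 # pyrrole
    "c1ccoc1",                                    # furan
    "c1ccsc1",                                    # thiophene
    "FC(F)(F)c1ccccc1",                           # benzotrifluoride
    "C#Cc1ccccc1",                                # phenylacetylene
    "N#Cc1ccccc1",                                # benzonitrile
    "CC(C)(C)OC(=O)N1CCC[C@H]1C(=O)O",            # Boc-proline
    "O=S(=O)(N)c1ccc(cc1)Cc1ccccc1",              # sulfonamide
)

_SCAFFOLDS: tuple[str, ...] = (
    "c1ccccc1{R}",
    "C1CCCCC1{R}",
    "c1ccncc1{R}",
    "c1ccc2ccccc2c1{R}",
    "C1CCC(CC1){R}",
    "c1cc(ccc1N){R}",
    "C(C)(C){R}",
    "CC(=O)N{R}",
    "c1ccc(cc1)O{R}",
    "C1CC1{R}",
    "c1csc(c1){R}",
    "C1CCOC1{R}",
)

_SUBSTITUENTS: tuple[str, ...] = (
    "C",
    "CC",
    "O",
    "N",
    "F",
    "Cl",
    "Br",
    "I",
    "C(=O)O",
    "C(=O)OC",
    "N(C)C",
    "C(F)(F)F",
    "S(=O)(=O)N",
    "C#N",
    "OC",
    "[N+](C)(C)C",
    "C(Cl)(Cl)Cl",
    "[13CH3]",
    "/C=C/C",
    "CC(C)C",
)


def fixture_smiles() -> list[str]:
    """Deterministic list of >=200 distinct valid SMILES strings.

    The curated drug list plus every scaffold x substituent combination,
    deduplicated while preserving order.
    """
    out: list[str] = list(DRUG_SMILES)
    for scaf in _SCAFFOLDS:
        for sub in _SUBSTITUENTS:
            out.append(scaf.format(R=sub))
    seen: set[str] = set()
    uniq = []
    for s in out:
        if s not in seen:
            seen.add(s)
            uniq.append(s)
    return uniq
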