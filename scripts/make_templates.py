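"""Regenerate the shipped monosaccharide template files.

Each template is derived from the package's own idealized chair
realization of the sugar: the 3D fixture is built, its ring identified
and stereo descriptors computed with the exact conventions of the
matching code, and the graph frozen into the text format under
src/glycograft/data/templates/.  Types are mock GLYCAM-like labels;
charges are the fixture's internally consistent mock set.

Run from the repository root:  python scripts/make_templates.py
"""

from pathlib import Path

from glycograft.fixtures import SUGARS, make_toy_pyranose
from glycograft.glycam_map import TemplateResidue, format_template, identify_monosaccharides

OUT = Path(__file__).resolve().parent.parent / "src" / "glycograft" / "data" / "templates"

# mock GLYCAM-like canonical atom types by fixture atom name pattern
def ff_type(name: str, element: str) -> str:
    if name == "O5":
        return "Os"
    if element == "O":
        return "O" if name == "O7" else "Oh"
    if element == "N":
        return "Ng"
    if element == "C":
        return "C" if name == "C7" else "Cg"
    # hydrogens
    if name.startswith("HO"):
        return "Ho"
    if name.startswith("HN"):
        return "Hn"
    return "Hc"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for sugar in sorted(SUGARS):
        for anomeric in ("alpha", "beta"):
            s, _centers = make_toy_pyranose(sugar=sugar, anomeric=anomeric)
            cands = identify_monosaccharides(s)
            assert len(cands) == 1, (sugar, anomeric, len(cands))
            cand = cands[0]
            assert cand.atoms == set(range(len(s.atoms))), "expansion missed atoms"
            name = f"{anomeric[0].upper()}{sugar}"
            atoms = [(a.name, a.element, ff_type(a.name, a.element), a.charge)
                     for a in s.atoms]
            bonds = sorted(
                (s.atoms[i].name, s.atoms[j].name)
                for i, j in (sorted(b) for b in s.bonds))
            t = TemplateResidue(
                name=name, sugar=sugar, anomeric_config=anomeric,
                ring_size=cand.ring_size, atoms=atoms, bonds=bonds,
                stereo_descriptors=cand.stereo)
            path = OUT / f"{name}.txt"
            path.write_text(format_template(t))
            print(f"wrote {path.name}: {len(atoms)} atoms, stereo {cand.stereo}")


if __name__ == "__main__":
    main()
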