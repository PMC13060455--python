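"""Regenerate the shipped restraint dictionary from the fragment templates.

Usage: python scripts/make_dictionary.py
"""

from pathlib import Path

import yaml

from qrcryst.restraints import build_dictionary_from_fragments


def main():
    out = Path(__file__).resolve().parents[1] / "src" / "qrcryst" / "data" / "restraints.yaml"
    d = build_dictionary_from_fragments()
    header = (
        "# Default restraint dictionary (harmonic bonds/angles per residue).\n"
        "# Ideal values measured from the fragment templates in qrcryst.fragments;\n"
        "# regenerate with scripts/make_dictionary.py.  Units: Å, degrees,\n"
        "# restraint-units Å^-2 / rad^-2.  Format per residue:\n"
        "#   bonds:  [atom_i, atom_j, ideal_length, force_constant]\n"
        "#   angles: [atom_i, apex, atom_k, ideal_degrees, force_constant]\n"
    )
    out.write_text(header + yaml.safe_dump(d, sort_keys=True))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
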