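"""Rebuild the bundled classic-network fixtures from canonical public sources.

Run from the repository root:

    python scripts/make_fixtures.py

Sources:

* ``zach`` — Zachary's karate club as shipped with networkx (Zachary 1977).
* ``florentine_marriage`` — Padgett's Florentine marriage network as shipped
  with networkx (15 tied families) plus the isolated Pucci family, giving
  the conventional 16-node version.
* ``florentine_business`` — Padgett's Florentine business network (PADGB),
  the canonical 15-edge list among the same 16 families, transcribed here.

The loader validates every fixture against its published motif counts at
load time, so a transcription error here cannot pass silently.
"""

from pathlib import Path

import networkx as nx

DATA = Path(__file__).resolve().parent.parent / "src" / "ergmselect" / "data"

FLORENTINE_FAMILIES = [
    "Acciaiuoli", "Albizzi", "Barbadori", "Bischeri", "Castellani", "Ginori",
    "Guadagni", "Lamberteschi", "Medici", "Pazzi", "Peruzzi", "Pucci",
    "Ridolfi", "Salviati", "Strozzi", "Tornabuoni",
]

# Padgett's business (PADGB) ties
FLORENTINE_BUSINESS_EDGES = [
    ("Barbadori", "Castellani"),
    ("Barbadori", "Ginori"),
    ("Barbadori", "Medici"),
    ("Barbadori", "Peruzzi"),
    ("Bischeri", "Guadagni"),
    ("Bischeri", "Lamberteschi"),
    ("Bischeri", "Peruzzi"),
    ("Castellani", "Lamberteschi"),
    ("Castellani", "Peruzzi"),
    ("Ginori", "Medici"),
    ("Guadagni", "Lamberteschi"),
    ("Lamberteschi", "Peruzzi"),
    ("Medici", "Pazzi"),
    ("Medici", "Salviati"),
    ("Medici", "Tornabuoni"),
]


def write_edges(path: Path, edges) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted((str(a), str(b)) for a, b in edges):
            fh.write(f"{a} {b}\n")


def write_nodes(path: Path, labels) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for lab in labels:
            fh.write(f"{lab}\n")


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)

    karate = nx.karate_club_graph()
    write_edges(DATA / "zach.edges", karate.edges())

    marriage = nx.florentine_families_graph()
    write_edges(DATA / "florentine_marriage.edges", marriage.edges())
    write_nodes(DATA / "florentine_marriage.nodes", FLORENTINE_FAMILIES)

    write_edges(DATA / "florentine_business.edges", FLORENTINE_BUSINESS_EDGES)
    write_nodes(DATA / "florentine_business.nodes", FLORENTINE_FAMILIES)

    print(f"wrote fixtures under {DATA}")


if __name__ == "__main__":
    main()
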