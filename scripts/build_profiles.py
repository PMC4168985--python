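"""Regenerate the bundled synthetic profile set under src/nescan/data/profiles/.

The matrices are synthetic stand-ins with realistic structure (template
identity, repressed conserved-position non-hydrophobics, strongly repressed
spacer prolines), anchored on the known template sequences and standard
scores.  Fixed per-class seeds keep the files reproducible.
"""

from pathlib import Path

from nescan.profiles import NesClass, write_profile
from nescan.simulate import make_toy_profile

OUT = Path(__file__).resolve().parent.parent / "src" / "nescan" / "data" / "profiles"

SEEDS = {
    NesClass.CLASS_1A3: 101,
    NesClass.CLASS_1B: 102,
    NesClass.CLASS_1C: 103,
    NesClass.CLASS_2: 104,
    NesClass.CLASS_1D: 105,
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for nes_class, seed in SEEDS.items():
        profile = make_toy_profile(nes_class, seed=seed)
        path = OUT / f"class_{nes_class.value}.tsv"
        write_profile(profile, path)
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
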