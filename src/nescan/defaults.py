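"""Bundled default activity profiles.

The packaged profile set under ``data/profiles/`` is synthetic: generated by
``scripts/build_profiles.py`` from :func:`nescan.simulate.make_toy_profile`,
anchored on the published template sequences and standard scores where those
are known (class 1b and 1c) and on designed class-consensus templates
elsewhere.  It exercises the full scoring pipeline; replace the profile
directory with measured matrices for production predictions.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

from .profiles import ActivityProfile, read_profile

#: classes shipped with the package (class 1d is bundled but disabled by
#: default in the scanner)
BUNDLED_CLASSES = ("1a3", "1b", "1c", "2", "1d")


def default_profile_dir() -> Path:
    return Path(str(files("nescan").joinpath("data/profiles")))


def default_profiles() -> list[ActivityProfile]:
    """Load the bundled synthetic profile set."""
    directory = default_profile_dir()
    return [
        read_profile(directory / f"class_{name}.tsv") for name in BUNDLED_CLASSES
    ]


def load_profile_dir(directory: str | Path) -> list[ActivityProfile]:
    """Load every ``*.tsv`` profile in a directory."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no profile files (*.tsv) in {directory}")
    return [read_profile(p) for p in paths]
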