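"""Shared plumbing for the numbered analysis drivers."""

import argparse
import os
import sys

from allelesplice.simulate import load_dataset


def make_parser(description: str) -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--seed", type=int, default=1, help="RNG seed")
    p.add_argument("--results", default="results", help="results directory")
    return p


def data_dir(args) -> str:
    return os.path.join(args.results, "data")


def require_dataset(args):
    d = data_dir(args)
    if not os.path.exists(os.path.join(d, "config.json")):
        sys.exit(f"no dataset under {d}: run analysis/01_simulate.py first")
    return load_dataset(d)


def require_table(args, relpath: str):
    from allelesplice.io import read_tsv

    path = os.path.join(args.results, relpath)
    if not os.path.exists(path):
        sys.exit(f"missing {path}: run the earlier analysis steps first")
    return read_tsv(path)
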