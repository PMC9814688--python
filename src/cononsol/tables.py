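"""Plain-text outputs: TSV tables with commented metadata headers,
extended-XYZ trajectory frames, and a hashed file manifest so any
result can be traced back to (config, seeds)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .umbrella import HistogramSet, PMFProfile


def _write_tsv(path: Path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a TSV written by this module, returning (table, metadata)."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, meta


def write_pmf(path: str | Path, pmf: PMFProfile, extra: dict | None = None
              ) -> None:
    df = pd.DataFrame({"rg_nm": pmf.rg_centers, "w_kj_mol": pmf.w,
                       "stderr_kj_mol": pmf.stderr})
    meta = {"temperature_K": pmf.temperature, "anchor": pmf.anchor}
    meta.update(extra or {})
    _write_tsv(Path(path), df, meta)


def write_histograms(path: str | Path, h: HistogramSet) -> None:
    cols = {"rg_nm": h.centers}
    for i, w in enumerate(h.windows):
        cols[f"win{i}"] = h.counts[i]
    meta = {"temperature_K": h.temperature,
            "rg0_nm": ",".join(f"{w.rg0:g}" for w in h.windows),
            "k_b_kj_mol_nm2": ",".join(f"{w.k_b:g}" for w in h.windows)}
    _write_tsv(Path(path), pd.DataFrame(cols), meta)


def write_xyz_frame(fh, positions: np.ndarray, labels, box: np.ndarray,
                    step: int = 0, energy: float | None = None) -> None:
    """Append one extended-XYZ frame (comment line carries step, box
    and total potential energy)."""
    fh.write(f"{len(positions)}\n")
    lattice = " ".join(f"{b:.6f}" for b in
                       [box[0], 0, 0, 0, box[1], 0, 0, 0, box[2]])
    comment = f'Lattice="{lattice}" step={step}'
    if energy is not None:
        comment += f" potential_kj_mol={energy:.6f}"
    fh.write(comment + "\n")
    for lab, p in zip(labels, positions):
        fh.write(f"{lab} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def read_xyz(path: str | Path) -> list[tuple[np.ndarray, dict]]:
    """Read all frames of an extended-XYZ file -> [(positions, info)]."""
    frames = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        info = {"comment": lines[i + 1]}
        pos = np.array([[float(x) for x in ln.split()[1:4]]
                        for ln in lines[i + 2:i + 2 + n]])
        frames.append((pos, info))
        i += 2 + n
    return frames


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_results_tables(results: dict[str, pd.DataFrame],
                         outdir: str | Path,
                         meta: dict | None = None) -> dict:
    """Write every result table as TSV and a JSON manifest.

    ``results`` maps a table name to a DataFrame; the manifest records
    each file's SHA-256 hash plus the supplied metadata (seed, config
    hash, ...), so any file can be regenerated and verified.  Returns
    the manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"meta": meta or {}, "files": {}}
    for name, df in results.items():
        path = outdir / f"{name}.tsv"
        _write_tsv(path, df, meta or {})
        manifest["files"][path.name] = sha256_file(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
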