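"""Readers and writers for compound tables, fingerprints, and results."""

from __future__ import annotations

import csv
import json

import numpy as np
import pandas as pd

from .datatypes import CompoundSet, SimilarityResult


def read_compound_table(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited compound table with columns id, smiles?, pki.

    Column matching is case-insensitive; the delimiter is sniffed from
    the file unless given.  Potencies must parse as finite numbers; a
    malformed row is reported with its (1-based, header-inclusive) line
    number.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, engine="python")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse compound table: {exc}") from exc

    cols = {c.lower().strip(): c for c in df.columns}
    if "id" not in cols or "pki" not in cols:
        missing = [c for c in ("id", "pki") if c not in cols]
        raise ValueError(
            f"{path}: missing required column(s) {', '.join(missing)} "
            f"(found: {', '.join(df.columns)})")

    out = pd.DataFrame({"id": df[cols["id"]].astype(str)})
    if "smiles" in cols:
        out["smiles"] = df[cols["smiles"]].astype(str)
    pki = pd.to_numeric(df[cols["pki"]], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(pki.to_numpy()))
    if bad.size:
        row = int(bad[0]) + 2  # +1 header, +1 one-based
        raise ValueError(
            f"{path}: malformed potency at line {row}: "
            f"{df[cols['pki']].iloc[bad[0]]!r}")
    out["pki"] = pki
    if out["id"].duplicated().any():
        dup = out["id"][out["id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate compound id {dup!r}")
    return out


def write_compound_table(cs: CompoundSet, path) -> None:
    df = pd.DataFrame({"id": cs.ids, "pki": cs.potencies})
    if cs.smiles is not None:
        df.insert(1, "smiles", cs.smiles)
    df.to_csv(path, index=False)


def read_fingerprints(path) -> dict[str, set[int]]:
    """Read a fingerprint file: one 'id<TAB>bit,bit,...' line per compound."""
    fps: dict[str, set[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                cid, bits = line.split("\t")
                fp = {int(b) for b in bits.split(",")}
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed fingerprint at line {lineno}") from exc
            if cid in fps:
                raise ValueError(f"{path}: duplicate id {cid!r} at line {lineno}")
            if not fp or min(fp) < 0:
                raise ValueError(
                    f"{path}: invalid bit set for {cid!r} at line {lineno}")
            fps[cid] = fp
    return fps


def write_fingerprints(cs: CompoundSet, path) -> None:
    with open(path, "w") as fh:
        for cid, fp in zip(cs.ids, cs.fingerprints):
            fh.write(f"{cid}\t{','.join(str(b) for b in sorted(fp))}\n")


def build_compound_set(table: pd.DataFrame,
                       fingerprints: dict[str, set[int]] | None = None) -> CompoundSet:
    """Assemble a CompoundSet from a table, computing ECFP4 bits if needed."""
    ids = table["id"].tolist()
    smiles = table["smiles"].tolist() if "smiles" in table.columns else None
    if fingerprints is not None:
        missing = [i for i in ids if i not in fingerprints]
        if missing:
            raise ValueError(
                f"fingerprint file lacks {len(missing)} compound(s), "
                f"first missing id: {missing[0]!r}")
        fps = [fingerprints[i] for i in ids]
    else:
        if smiles is None:
            raise ValueError(
                "compound table has no smiles column; supply a fingerprint file")
        from .chemspace import compute_fingerprints
        fps = compute_fingerprints(smiles)
    return CompoundSet(ids=ids, smiles=smiles, fingerprints=fps,
                       potencies=table["pki"].to_numpy())


def write_projection(ids: list[str], coords: np.ndarray, path) -> None:
    pd.DataFrame({"id": ids, "x": coords[:, 0], "y": coords[:, 1]}).to_csv(
        path, index=False)


def write_similarity_csv(results: list[SimilarityResult], path,
                         precision: int | None = None) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id_a", "id_b", "re", "cd"])
        for r in results:
            if precision is None:
                writer.writerow([r.id_a, r.id_b, repr(r.re), repr(r.cd)])
            else:
                writer.writerow(
                    [r.id_a, r.id_b, f"{r.re:.{precision}f}", f"{r.cd:.{precision}f}"])


def write_similarity_json(results: list[SimilarityResult], path, *,
                          epsilon: float, log_base: str, grid: str) -> None:
    payload = {
        "metadata": {"epsilon": epsilon, "log_base": log_base, "grid": grid},
        "pairs": [
            {"id_a": r.id_a, "id_b": r.id_b, "re": r.re, "cd": r.cd}
            for r in results
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2)
        fh.write("\n")


def write_manifest(path, *, config: dict, seed: int, inputs: dict) -> None:
    """Record everything needed to replay a run: config, seed, versions."""
    import sklearn
    from . import __version__

    payload = {
        "alsim_version": __version__,
        "numpy_version": np.__version__,
        "sklearn_version": sklearn.__version__,
        "config": config,
        "seed": seed,
        "inputs": inputs,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2)
        fh.write("\n")
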