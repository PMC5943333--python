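"""Genepop file I/O (2- and 3-digit dialects) with a metadata sidecar.

The Genepop layout: a free title line, one locus name per line (or one
comma-separated line), then ``Pop`` blocks of individual lines
``id , 001002 003003 ...``.  ``00``/``000`` encodes a missing allele.
A tab-separated sidecar carries the metadata an AlleleMatrix needs beyond
what Genepop can express (stream, position, side).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, META_COLUMNS, AlleleMatrix, simple_metadata, concat_matrices


class GenepopParseError(ValueError):
    pass


def write_genepop(
    matrix: AlleleMatrix,
    path: str | Path,
    digits: int = 3,
    title: str | None = None,
    offset: int = 0,
) -> None:
    """Write one ``Pop`` block per pool, preserving individual order.

    ``offset`` is added to every non-missing allele state on output (some
    conventions store repeat classes as size-like codes, e.g. +100); the
    default 0 keeps write/read round-trips lossless.
    """
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    if matrix.n_individuals == 0:
        raise ValueError("cannot write an empty matrix")
    hi = matrix.genotypes.max() + (offset if matrix.genotypes.max() > 0 else 0)
    if hi >= 10**digits:
        raise ValueError(f"allele state {hi} does not fit in {digits} digits")
    lines = [title if title is not None else "riverdrift genotypes"]
    lines.extend(matrix.locus_names)
    for pool_label in matrix.pools:
        lines.append("Pop")
        mask = (matrix.individuals["pool"] == pool_label).to_numpy()
        ids = matrix.individuals.loc[mask, "id"].tolist()
        genos = matrix.genotypes[mask]
        for ind_id, row in zip(ids, genos):
            fields = []
            for a, b in row:
                a_out = a + offset if a != MISSING else 0
                b_out = b + offset if b != MISSING else 0
                fields.append(f"{a_out:0{digits}d}{b_out:0{digits}d}")
            lines.append(f"{ind_id} ,  " + " ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path: str | Path, offset: int = 0) -> AlleleMatrix:
    """Parse a Genepop file into an AlleleMatrix (one pool per Pop block).

    ``offset`` is subtracted from every non-missing allele code, matching
    the ``offset`` used at write time.
    """
    raw = Path(path).read_text().splitlines()
    if len(raw) < 3:
        raise GenepopParseError(f"{path}: too short to be a Genepop file")
    body = raw[1:]

    locus_names: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        line = body[i].strip()
        if line:
            locus_names.extend(s.strip() for s in line.split(",") if s.strip())
        i += 1
    if not locus_names:
        raise GenepopParseError(f"{path}: no locus names before first Pop")
    if i == len(body):
        raise GenepopParseError(f"{path}: no Pop separator found")

    n_loci = len(locus_names)
    digit_width: int | None = None
    pools: list[list[tuple[str, list[int]]]] = []
    for lineno_body, line in enumerate(body[i:], start=i + 2):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            pools.append([])
            continue
        if "," not in stripped:
            raise GenepopParseError(
                f"{path}:{lineno_body}: expected 'id , genotypes' (missing comma)"
            )
        ind_id, _, geno_part = stripped.partition(",")
        ind_id = ind_id.strip()
        fields = geno_part.split()
        if len(fields) != n_loci:
            raise GenepopParseError(
                f"{path}:{lineno_body}: expected {n_loci} genotype fields, got {len(fields)}"
            )
        alleles: list[int] = []
        for f in fields:
            if len(f) % 2 != 0 or not f.isdigit():
                raise GenepopParseError(f"{path}:{lineno_body}: malformed genotype {f!r}")
            w = len(f) // 2
            if w not in (2, 3):
                raise GenepopParseError(f"{path}:{lineno_body}: allele width {w} not 2 or 3")
            if digit_width is None:
                digit_width = w
            elif w != digit_width:
                raise GenepopParseError(
                    f"{path}:{lineno_body}: inconsistent allele digit width ({w} vs {digit_width})"
                )
            a, b = int(f[:w]), int(f[w:])
            if (a == 0) != (b == 0):
                raise GenepopParseError(
                    f"{path}:{lineno_body}: half-missing genotype {f!r}"
                )
            alleles.extend(
                (a - offset if a else MISSING, b - offset if b else MISSING)
            )
        pools[-1].append((ind_id, alleles))

    blocks = []
    for p_idx, members in enumerate(pools):
        if not members:
            continue
        label = f"pop{p_idx + 1}"
        genos = np.array([m[1] for m in members], dtype=np.int64).reshape(len(members), n_loci, 2)
        meta = simple_metadata(len(members), pool_label=label)
        meta["id"] = [m[0] for m in members]
        blocks.append(AlleleMatrix(meta, genos, list(locus_names)))
    if not blocks:
        raise GenepopParseError(f"{path}: no individuals found")
    return concat_matrices(blocks)


def write_metadata(matrix: AlleleMatrix, path: str | Path) -> None:
    matrix.individuals[META_COLUMNS].to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata sidecar missing columns: {sorted(missing)}")
    return meta


def attach_metadata(matrix: AlleleMatrix, meta: pd.DataFrame) -> AlleleMatrix:
    """Replace placeholder metadata from Genepop with a sidecar table, by id."""
    merged = meta.set_index("id").loc[matrix.individuals["id"]].reset_index()
    return AlleleMatrix(merged[META_COLUMNS], matrix.genotypes.copy(), list(matrix.locus_names))
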