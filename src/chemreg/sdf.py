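"""SD-file (MDL V2000) reading/writing and bulk import/export.

Records are framed by ``$$$$`` lines; each record is a molfile connection
table followed by ``> <tag>`` property blocks whose values may span
multiple lines (terminated by a blank line). Reading is lazy and
fault-contained: a malformed record yields a :class:`FormatError` *item*
and iteration continues with the next record, so one bad entry cannot
poison a bulk import. Property order is preserved.

Import maps property tags to compound fields and saves each record as one
compound through the registry (structure dedup applies); a mol block with
disconnected fragments is imported as a mixture — one composition per
component, percentages unset. Export writes one record per compound with
a single (possibly multi-fragment) mol block.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from rdkit import Chem, rdBase

from .chem import Molecule, parse_structure
from .errors import AbortError, ChemregError, FormatError
from .registry import CompoundDraft, Registry

__all__ = ["SdfRecord", "ImportReport", "read_sdf", "write_sdf_record",
           "import_compounds", "export_compounds", "PERCENTAGE_TAG"]

PERCENTAGE_TAG = "percentages"


@dataclass
class SdfRecord:
    mol_block: str
    properties: dict[str, str] = field(default_factory=dict)  # ordered
    index: int = 0


@dataclass
class ImportReport:
    records_read: int = 0
    compounds_created: int = 0
    structures_created: int = 0
    structures_reused: int = 0
    failures: list[tuple[int, str]] = field(default_factory=list)


def read_sdf(stream) -> "iter[SdfRecord | FormatError]":
    """Lazily iterate the records of an SD-file text stream.

    Yields :class:`SdfRecord` for well-formed records and
    :class:`FormatError` instances for malformed ones (e.g. a truncated
    final record without ``$$$$``); iteration always resumes at the next
    record delimiter.
    """
    index = 0
    lines: list[str] = []
    terminated = False
    for raw in stream:
        line = raw.rstrip("\r\n")
        if line.strip() == "$$$$":
            yield _parse_record(lines, index)
            index += 1
            lines = []
            terminated = True
            continue
        terminated = False
        lines.append(line)
    if lines and any(l.strip() for l in lines):
        # trailing content with no $$$$ terminator
        yield FormatError("truncated record: missing '$$$$' terminator",
                          record_index=index)
    _ = terminated


def _parse_record(lines: list[str], index: int) -> SdfRecord | FormatError:
    end = None
    for i, line in enumerate(lines):
        if line.strip() == "M  END":
            end = i
            break
    if end is None:
        return FormatError("record has no 'M  END' molfile terminator",
                           record_index=index)
    mol_block = "\n".join(lines[:end + 1]) + "\n"
    props: dict[str, str] = {}
    i = end + 1
    n = len(lines)
    while i < n:
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if not line.startswith(">"):
            return FormatError(
                f"unexpected content in data block: {line!r}",
                record_index=index)
        tag = _parse_tag(line)
        if tag is None:
            return FormatError(f"malformed data header: {line!r}",
                               record_index=index)
        i += 1
        value_lines = []
        while i < n and lines[i].strip() != "":
            value_lines.append(lines[i])
            i += 1
        props[tag] = "\n".join(value_lines)
    return SdfRecord(mol_block=mol_block, properties=props, index=index)


def _parse_tag(line: str) -> str | None:
    lt = line.find("<")
    gt = line.find(">", lt + 1)
    if lt == -1 or gt == -1:
        return None
    return line[lt + 1:gt]


def write_sdf_record(stream, mol_block: str, properties: dict[str, str]
                     ) -> None:
    if not mol_block.endswith("\n"):
        mol_block += "\n"
    stream.write(mol_block)
    for tag, value in properties.items():
        stream.write(f"> <{tag}>\n{value}\n\n")
    stream.write("$$$$\n")


def import_compounds(registry: Registry, type_name: str, stream,
                     mapping: dict[str, str], actor: str,
                     policy: str = "skip",
                     name_generator=None) -> ImportReport:
    """Import an SD-file as compounds of ``type_name``.

    ``mapping`` maps SD property tags to compound fields (standard fields
    ``compound_name``/``cas``/``read_role``, registered extra columns, or
    the special ``percentages`` field carrying per-component percentages
    as whitespace-separated values with ``-`` for unset). Records without
    a mapped ``compound_name`` need a ``name_generator(index, record)``.

    ``policy``: ``skip`` records failures and continues; ``abort`` raises
    :class:`AbortError` on the first failure (already-imported records of
    this call remain — each record is saved in its own transaction).
    """
    if policy not in ("skip", "abort"):
        raise ValueError(f"unknown import policy {policy!r}")
    maps_name = "compound_name" in mapping.values()
    if not maps_name and name_generator is None:
        raise ValueError("mapping must cover compound_name or a "
                         "name_generator must be given")
    ct = registry.store.compound_types[type_name]
    extra_fields = {n for n, _ in ct.extra_columns}
    report = ImportReport()
    for item in read_sdf(stream):
        report.records_read += 1
        if isinstance(item, FormatError):
            report.failures.append((item.record_index or 0, str(item)))
            if policy == "abort":
                raise AbortError(str(item),
                                 record_index=item.record_index,
                                 report=report)
            continue
        try:
            draft = _record_to_draft(item, mapping, extra_fields,
                                     name_generator)
            outcome = registry.save_compound(type_name, draft, actor)
        except ChemregError as exc:
            report.failures.append((item.index, str(exc)))
            if policy == "abort":
                raise AbortError(str(exc), record_index=item.index,
                                 report=report) from exc
            continue
        report.compounds_created += 1
        report.structures_created += outcome.structures_created
        report.structures_reused += outcome.structures_reused
    return report


def _record_to_draft(record: SdfRecord, mapping: dict[str, str],
                     extra_fields: set[str], name_generator) -> CompoundDraft:
    mol = parse_structure(record.mol_block, format="molfile")
    draft = CompoundDraft(compositions=[])
    extra: dict = {}
    percentages: list[float | None] | None = None
    for tag, value in record.properties.items():
        fld = mapping.get(tag)
        if fld is None:
            continue
        if fld == "compound_name":
            draft.compound_name = value
        elif fld == "cas":
            draft.cas = value or None
        elif fld == "read_role":
            draft.read_role = value or None
        elif fld == PERCENTAGE_TAG:
            percentages = [None if tok == "-" else float(tok)
                           for tok in value.split()]
        elif fld in extra_fields:
            extra[fld] = value
        # unmapped / undeclared tags are ignored
    draft.extra = extra
    if draft.compound_name is None and name_generator is not None:
        draft.compound_name = name_generator(record.index, record)
    # split in input order so percentage lists align with the mol block
    from .chem import split_components
    parts = [Chem.MolToSmiles(p.rdmol) for p in split_components(mol)]
    if percentages is not None and len(percentages) == len(parts):
        draft.compositions = list(zip(parts, percentages))
    else:
        draft.compositions = [(p, None) for p in parts]
    return draft


def export_compounds(compounds, stream,
                     fields: list[str] | None = None) -> int:
    """Write compound records (dicts from ``Registry.get_compound``) as an
    SD-file. Multi-component compounds become a single multi-fragment mol
    block; per-component percentages are written under the
    ``percentages`` tag when any is set. Returns the count written."""
    fields = fields or ["compound_name", "cas"]
    written = 0
    for record in compounds:
        comps = record["compositions"]
        mols = [parse_structure(c["structure_text"]).rdmol for c in comps]
        combined = mols[0]
        for m in mols[1:]:
            combined = Chem.CombineMols(combined, m)
        with rdBase.BlockLogs():
            block = Chem.MolToMolBlock(combined, kekulize=True)
        props: dict[str, str] = {}
        for fld in fields:
            value = record.get(fld)
            if value is not None:
                props[fld] = str(value)
        if any(c["percentage"] is not None for c in comps):
            props[PERCENTAGE_TAG] = " ".join(
                "-" if c["percentage"] is None else repr(c["percentage"])
                for c in comps)
        write_sdf_record(stream, block, props)
        written += 1
    return written
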