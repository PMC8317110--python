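"""Result writers: tab-separated text, mirGFF3 and a self-contained HTML page.

All three formats are derived from the same quantified hits, so expression
values agree across them.  Row order is deterministic: category (wildtype,
then NTA), then license plate lexicographically; variant-containing isomiRs
go to a separate file, with no exclusivity or repeat information, mirroring
how they are computed.

The TSV is the lossless machine-readable form: :func:`parse_tsv` rebuilds
every hit field from it given the lookup-table bundle (needed to resolve
placement references back to expanded precursors).
"""

from __future__ import annotations

import html as _html
from pathlib import Path
from typing import Sequence

from .profiler import IsomirHit, RunSummary
from .reference import offset_label
from .tables import LookupTableBundle, _parse_placements, _placements_str

__all__ = ["write_tsv", "parse_tsv", "write_gff3", "write_html", "MAIN_COLUMNS", "VARIANT_COLUMNS"]

MAIN_COLUMNS = [
    "license_plate", "sequence", "templated_core", "type", "exclusive",
    "repeat_classes", "placements", "offset_labels", "genome_labels",
    "raw_count", "rpm_all", "rpm_mapped",
]
VARIANT_COLUMNS = [
    "license_plate", "sequence", "templated_core", "type", "variant_ids",
    "placements", "offset_labels", "genome_labels",
    "raw_count", "rpm_all", "rpm_mapped",
]

_CATEGORY_ORDER = {"wildtype": 0, "nta": 1, "variant": 2}


def _type_field(hit: IsomirHit) -> str:
    """Type column; for NTA molecules it names the added nucleotide and length."""
    if hit.category == "nta":
        return f"nta:{hit.tail[0]}{len(hit.tail)}"
    return hit.category


def _sorted_hits(hits: Sequence[IsomirHit]) -> list[IsomirHit]:
    return sorted(hits, key=lambda h: (_CATEGORY_ORDER[h.category], str(h.plate)))


def _summary_lines(summary: RunSummary) -> list[str]:
    pct = summary.percentages()
    lines = [
        f"# total_reads\t{summary.total_reads}",
        f"# mapped_exclusive\t{summary.mapped_exclusive}",
        f"# mapped_ambiguous\t{summary.mapped_ambiguous}",
        f"# mapped_variant\t{summary.mapped_variant}",
        f"# nta_rescued\t{summary.nta_rescued}",
        f"# unmapped\t{summary.unmapped}",
        f"# filtered_with_n\t{summary.filtered_with_n}",
        f"# filtered_too_short\t{summary.filtered_too_short}",
        f"# pct_exclusive\t{pct['exclusive']:.4f}",
        f"# pct_ambiguous\t{pct['ambiguous']:.4f}",
        f"# pct_variant\t{pct['variant']:.4f}",
        f"# pct_nta\t{pct['nta']:.4f}",
        f"# pct_unmapped\t{pct['unmapped']:.4f}",
    ]
    if summary.zero_mapped_note:
        lines.append("# note\tno reads mapped; rpm_mapped values are reported as zero")
    return lines


def write_tsv(hits: Sequence[IsomirHit], summary: RunSummary, out_prefix: str | Path) -> list[Path]:
    """Write ``<prefix>.isomirs.tsv`` (wildtype + NTA) and ``<prefix>.variants.tsv``.

    Floats are written with Python's shortest round-trip repr so a re-parse
    reproduces them exactly.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    main_path = out_prefix.with_name(out_prefix.name + ".isomirs.tsv")
    var_path = out_prefix.with_name(out_prefix.name + ".variants.tsv")
    ordered = _sorted_hits(hits)

    with open(main_path, "w") as fh:
        for line in _summary_lines(summary):
            fh.write(line + "\n")
        fh.write("\t".join(MAIN_COLUMNS) + "\n")
        for h in ordered:
            if h.category == "variant":
                continue
            fh.write(
                "\t".join(
                    [
                        str(h.plate), h.read_seq, h.templated_core, _type_field(h),
                        h.exclusive or "", ",".join(h.repeat_classes or []),
                        _placements_str(h.placements), ";".join(h.offset_labels),
                        ";".join(h.genome_labels), str(h.raw_count),
                        str(h.rpm_all), str(h.rpm_mapped),
                    ]
                )
                + "\n"
            )
    with open(var_path, "w") as fh:
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for h in ordered:
            if h.category != "variant":
                continue
            fh.write(
                "\t".join(
                    [
                        str(h.plate), h.read_seq, h.templated_core, _type_field(h),
                        ";".join(f"{s}:{v}" for s, v in h.variant_ids),
                        _placements_str(h.placements), ";".join(h.offset_labels),
                        ";".join(h.genome_labels), str(h.raw_count),
                        str(h.rpm_all), str(h.rpm_mapped),
                    ]
                )
                + "\n"
            )
    return [main_path, var_path]


def parse_tsv(out_prefix: str | Path, bundle: LookupTableBundle) -> list[IsomirHit]:
    """Rebuild hits from the TSV pair written by :func:`write_tsv`."""
    out_prefix = Path(out_prefix)
    hits: list[IsomirHit] = []
    main_path = out_prefix.with_name(out_prefix.name + ".isomirs.tsv")
    var_path = out_prefix.with_name(out_prefix.name + ".variants.tsv")
    with open(main_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("license_plate\t"):
                continue
            (_, seq, core, typ, excl, rcls, pls, _, _, cnt, rpm_a, rpm_m) = line.split("\t")
            tail = seq[len(core):] if typ.startswith("nta:") else ""
            hits.append(
                IsomirHit(
                    read_seq=seq,
                    category="nta" if typ.startswith("nta:") else "wildtype",
                    templated_core=core,
                    tail=tail,
                    placements=_parse_placements(pls, bundle.expanded),
                    exclusive=excl or None,
                    repeat_classes=rcls.split(",") if rcls else [],
                    variant_ids=[],
                    raw_count=int(cnt),
                    rpm_all=float(rpm_a),
                    rpm_mapped=float(rpm_m),
                )
            )
    with open(var_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("license_plate\t"):
                continue
            (_, seq, core, typ, vids, pls, _, _, cnt, rpm_a, rpm_m) = line.split("\t")
            pairs = [tuple(e.split(":", 1)) for e in vids.split(";")] if vids else []
            hits.append(
                IsomirHit(
                    read_seq=seq,
                    category="variant",
                    templated_core=core,
                    tail="",
                    placements=_parse_placements(pls, bundle.expanded),
                    exclusive=None,
                    repeat_classes=None,
                    variant_ids=pairs,
                    raw_count=int(cnt),
                    rpm_all=float(rpm_a),
                    rpm_mapped=float(rpm_m),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# mirGFF3


def _variant_attribute(hit: IsomirHit, placement) -> tuple[str, str | None]:
    """(Variant attribute, offset label used as Name) for one placement.

    mirGFF3 controlled vocabulary, with signs mapped from the d5/d3 offset
    convention: ``iso_5p:+N`` means N nucleotides *gained* at the 5' end
    (our d5 = -N, start upstream of the reference), ``iso_3p:+N`` means N
    templated nucleotides gained at the 3' end (our d3 = +N); ``iso_add3p:N``
    is an N-nt non-templated 3' addition; ``iso_snv`` flags a sequence
    variant.  A reference-identical isomiR gets Variant=NA.
    """
    terms: list[str] = []
    name = None
    matures = placement.precursor.parent.matures
    for m in matures:
        m_start, m_end = placement.precursor.mature_span(m)
        if placement.start <= m_end and m_start <= placement.end:
            d5 = placement.start - m_start
            d3 = placement.end - m_end
            name = offset_label(m, placement)
            if d5:
                terms.append(f"iso_5p:{'+' if d5 < 0 else '-'}{abs(d5)}")
            if d3:
                terms.append(f"iso_3p:{'+' if d3 > 0 else '-'}{abs(d3)}")
            break
    if hit.category == "nta":
        terms.append(f"iso_add3p:{len(hit.tail)}")
    if hit.category == "variant":
        terms.append("iso_snv")
    return (",".join(terms) if terms else "NA"), name


def write_gff3(hits: Sequence[IsomirHit], path: str | Path) -> Path:
    """One mirGFF3 feature line per (sequence, precursor placement).

    Coordinates are given on the un-expanded precursor whenever the isomiR
    fits inside it (seqid = database precursor name); otherwise on the
    flank-expanded precursor with a ``&WithFlank`` seqid.
    """
    path = Path(path)
    lines = ["##gff-version 3", "## mirGFF3-compatible isomiR expression output"]
    for h in _sorted_hits(hits):
        for i, pl in enumerate(h.placements, 1):
            xp = pl.precursor
            flank5 = xp.flank5
            parent_len = xp.parent.length
            if pl.start > flank5 and pl.end <= flank5 + parent_len:
                seqid = xp.parent.name
                start, end = pl.start - flank5, pl.end - flank5
            else:
                seqid = f"{xp.parent.name}&WithFlank"
                start, end = pl.start, pl.end
            variant_attr, name = _variant_attribute(h, pl)
            ftype = "ref_miRNA" if (h.category == "wildtype" and variant_attr == "NA" and name) else "isomiR"
            attrs = [
                f"ID={h.plate}.{i}",
                f"Read={h.read_seq}",
                f"UID={h.plate}",
                f"Name={name or h.plate}",
                f"Parent={xp.parent.name}",
                f"Variant={variant_attr}",
                f"Expression={h.raw_count}",
                "Filter=Pass",
            ]
            lines.append(
                "\t".join(
                    [seqid, "isomirkit", ftype, str(start), str(end), ".", "+", ".",
                     ";".join(attrs)]
                )
            )
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# HTML overview


_SORT_SCRIPT = """
function sortIsomirTable(idx, numeric) {
  var tb = document.getElementById('isomir-table').tBodies[0];
  var rows = Array.prototype.slice.call(tb.rows);
  rows.sort(function (r1, r2) {
    var a = r1.cells[idx].textContent;
    var b = r2.cells[idx].textContent;
    if (numeric) { return parseFloat(b) - parseFloat(a); }
    return a.localeCompare(b);
  });
  rows.forEach(function (r) { tb.appendChild(r); });
}
"""


def _esc(text: str) -> str:
    return _html.escape(str(text), quote=True)


def _precursor_detail(xp, placement_hits) -> str:
    """An alignment block: isomiRs rendered in register under their precursor.

    Mature-reference spans of every database are marked with ``=`` rails so
    the reader can see each collection's reference miRNA at a glance.
    """
    lines = [f"{xp.sequence}  {_esc(xp.parent.name)} ({xp.parent.db_tag}, expanded)"]
    for m in xp.parent.matures:
        m_start, m_end = xp.mature_span(m)
        rail = " " * (m_start - 1) + "=" * (m_end - m_start + 1)
        lines.append(f"{rail:<{len(xp.sequence)}}  {_esc(m.name)} (reference)")
    for hit, pl in placement_hits:
        padded = " " * (pl.start - 1) + hit.templated_core + hit.tail.lower()
        label = f"{hit.plate} {_type_field(hit)} n={hit.raw_count}"
        lines.append(f"{padded:<{len(xp.sequence)}}  {_esc(label)}")
    return "\n".join(lines)


def write_html(hits: Sequence[IsomirHit], summary: RunSummary, path: str | Path) -> Path:
    """Self-contained overview page: run summary, sortable isomiR table,
    and per-precursor alignment details."""
    path = Path(path)
    ordered = _sorted_hits(hits)
    pct = summary.percentages()

    summary_rows = "".join(
        f"<tr><td>{_esc(k)}</td><td>{_esc(v)}</td></tr>"
        for k, v in [
            ("Total reads", summary.total_reads),
            ("Mapped exclusively", f"{summary.mapped_exclusive} ({pct['exclusive']:.2f}%)"),
            ("Mapped ambiguously", f"{summary.mapped_ambiguous} ({pct['ambiguous']:.2f}%)"),
            ("Mapped with variants", f"{summary.mapped_variant} ({pct['variant']:.2f}%)"),
            ("Rescued as 3' NTA", f"{summary.nta_rescued} ({pct['nta']:.2f}%)"),
            ("Unmapped", f"{summary.unmapped} ({pct['unmapped']:.2f}%)"),
            ("Filtered (N)", summary.filtered_with_n),
            ("Filtered (too short)", summary.filtered_too_short),
        ]
    )

    headers = [
        ("License plate", 0), ("Sequence", 1), ("Type", 2), ("Exclusive", 3),
        ("Repeats", 4), ("Labels", 5), ("Count", 6), ("RPM (all)", 7), ("RPM (mapped)", 8),
    ]
    head_cells = "".join(
        f'<th onclick="sortIsomirTable({i}, {str(i >= 6).lower()})">{_esc(h)}</th>'
        for h, i in headers
    )
    body_rows = []
    for h in ordered:
        labels = "<br/>".join(_esc(l) for l in h.offset_labels) or _esc(str(h.plate))
        body_rows.append(
            "<tr>"
            f"<td>{_esc(h.plate)}</td><td class='seq'>{_esc(h.read_seq)}</td>"
            f"<td>{_esc(_type_field(h))}</td><td>{_esc(h.exclusive or '-')}</td>"
            f"<td>{_esc(','.join(h.repeat_classes or []) or '-')}</td>"
            f"<td>{labels}</td><td>{h.raw_count}</td>"
            f"<td>{h.rpm_all:.2f}</td><td>{h.rpm_mapped:.2f}</td>"
            "</tr>"
        )

    by_precursor: dict[tuple[str, str], list] = {}
    for h in ordered:
        for pl in h.placements:
            key = (pl.precursor.parent.db_tag, pl.precursor.parent.name)
            by_precursor.setdefault(key, []).append((h, pl))
    details = []
    for key in sorted(by_precursor):
        xp = by_precursor[key][0][1].precursor
        details.append(
            f"<h3>{_esc(xp.parent.name)} ({_esc(xp.parent.db_tag)})</h3>"
            f"<pre>{_precursor_detail(xp, by_precursor[key])}</pre>"
        )

    doc = f"""<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8"/>
<title>isomirkit profile</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; }}
th, td {{ border: 1px solid #999; padding: 4px 8px; font-size: 90%; }}
th {{ background: #eee; cursor: pointer; }}
td.seq, pre {{ font-family: monospace; }}
</style>
<script>{_SORT_SCRIPT}</script>
</head>
<body>
<h1>isomiR profile</h1>
<h2>Run summary</h2>
<table>{summary_rows}</table>
<h2>isomiRs ({len(ordered)} distinct sequences)</h2>
<table id="isomir-table">
<thead><tr>{head_cells}</tr></thead>
<tbody>
{chr(10).join(body_rows)}
</tbody>
</table>
<h2>Per-precursor detail</h2>
{chr(10).join(details) or "<p>No mapped isomiRs.</p>"}
</body>
</html>
"""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(doc)
    return path
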