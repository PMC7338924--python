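"""Readers, writers and run manifests.

Posts travel as JSON-lines (pushshift-style field names accepted via a
field mapping), taxonomies as YAML or CSV, tabular results as CSV, and
every pipeline run writes a manifest recording input hashes, parameters
and seeds so outputs are reproducible from the manifest alone.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

from .taxonomy import DisambiguationRule, KeywordTaxonomy, Post

__all__ = [
    "PUSHSHIFT_FIELDS",
    "read_posts",
    "write_posts",
    "read_taxonomy",
    "write_taxonomy",
    "Manifest",
]

PUSHSHIFT_FIELDS = {
    "post_id": "id",
    "user_id": "author",
    "created_utc": "created_utc",
    "text": "text",
}


def read_posts(
    path: str | Path,
    field_mapping: Mapping[str, str] = PUSHSHIFT_FIELDS,
    stats: dict[str, int] | None = None,
) -> Iterator[Post]:
    """Stream posts from a JSON-lines file in constant memory.

    Malformed lines and lines missing a mapped field are skipped and
    counted in ``stats`` (keys ``read``, ``skipped``)."""
    s = stats if stats is not None else {}
    s.setdefault("read", 0)
    s.setdefault("skipped", 0)
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            s["read"] += 1
            try:
                obj = json.loads(line)
                yield Post(
                    post_id=str(obj[field_mapping["post_id"]]),
                    user_id=str(obj[field_mapping["user_id"]]),
                    created_utc=int(obj[field_mapping["created_utc"]]),
                    text=str(obj[field_mapping["text"]]),
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError):
                s["skipped"] += 1


def write_posts(
    posts: Iterable[Post],
    path: str | Path,
    field_mapping: Mapping[str, str] = PUSHSHIFT_FIELDS,
) -> int:
    """Write posts as JSON-lines; returns the number written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            obj = {
                field_mapping["post_id"]: p.post_id,
                field_mapping["user_id"]: p.user_id,
                field_mapping["created_utc"]: p.created_utc,
                field_mapping["text"]: p.text,
            }
            fh.write(json.dumps(obj, sort_keys=True) + "\n")
            n += 1
    return n


def write_taxonomy(taxonomy: KeywordTaxonomy, path: str | Path) -> None:
    """Serialize a taxonomy to YAML (or CSV if the suffix is .csv)."""
    path = Path(path)
    if path.suffix == ".csv":
        rules = {r.ambiguous_keyword: r for r in taxonomy.disambiguation_rules}
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["taxonomy", "category", "keyword", "ambiguous_flag",
                        "context_list"])
            for cat, kws in taxonomy.categories.items():
                for kw in kws:
                    rule = rules.get(kw)
                    w.writerow([
                        taxonomy.name, cat, kw,
                        int(rule is not None),
                        "|".join(rule.context_keywords) if rule else "",
                    ])
        return
    doc = {
        "name": taxonomy.name,
        "categories": {c: list(k) for c, k in taxonomy.categories.items()},
        "disambiguation_rules": [
            {"keyword": r.ambiguous_keyword,
             "context_keywords": list(r.context_keywords)}
            for r in taxonomy.disambiguation_rules
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def read_taxonomy(path: str | Path, validate: bool = True) -> KeywordTaxonomy:
    """Load a taxonomy from YAML or CSV and (by default) validate it."""
    path = Path(path)
    if path.suffix == ".csv":
        categories: dict[str, list[str]] = {}
        rules: list[DisambiguationRule] = []
        name = "taxonomy"
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                name = row["taxonomy"]
                categories.setdefault(row["category"], []).append(row["keyword"])
                if row.get("ambiguous_flag") in ("1", "true", "True"):
                    rules.append(
                        DisambiguationRule(
                            row["keyword"],
                            tuple(row["context_list"].split("|")),
                        )
                    )
        tax = KeywordTaxonomy(name, categories, rules)
    else:
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        tax = KeywordTaxonomy(
            doc["name"],
            {c: list(k) for c, k in doc["categories"].items()},
            [
                DisambiguationRule(r["keyword"], tuple(r["context_keywords"]))
                for r in doc.get("disambiguation_rules", []) or []
            ],
        )
    return tax.validate() if validate else tax


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Manifest:
    """Provenance record for one pipeline run."""

    parameters: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)
    stages_completed: list = field(default_factory=list)
    counters: dict = field(default_factory=dict)

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = sha256_file(path)

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = sha256_file(path)

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, path: str | Path) -> "Manifest":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))
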