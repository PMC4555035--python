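"""Drug-target tables: ingestion, labelling, filtering and split hygiene.

A drug record carries a raw legal-status string from the source database,
its simplified class label, the set of protein targets, and optionally
per-target binding affinities (IC50, nM) and — for problematic drugs — the
reason development failed.  Labels follow the policy: marketed or
obtainable-by-prescription compounds (including controlled substances
listed as "illicit") are *approved*; compounds withdrawn from the market or
halted in development over safety or efficacy are *problematic*; everything
still in the pipeline is *experimental*.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .network import ProteinNetwork

__all__ = [
    "DrugRecord",
    "LabeledDataset",
    "DEFAULT_STATUS_MAP",
    "load_drug_targets",
    "assign_label",
    "filter_affinity",
    "restrict_to_networks",
    "dedupe_conflicting",
    "split_train_test",
    "remove_failure_group",
    "write_drug_targets",
]

APPROVED = "approved"
PROBLEMATIC = "problematic"
EXPERIMENTAL = "experimental"

DEFAULT_STATUS_MAP: dict[str, str] = {
    "approved": APPROVED,
    "otc": APPROVED,
    "prescription": APPROVED,
    "illicit": APPROVED,  # in practice: controlled substances, obtainable by prescription
    "controlled": APPROVED,
    "withdrawn": PROBLEMATIC,
    "discontinued": PROBLEMATIC,
    "halted": PROBLEMATIC,
    "safety": PROBLEMATIC,
    "efficacy-failure": PROBLEMATIC,
    "experimental": EXPERIMENTAL,
    "investigational": EXPERIMENTAL,
    "preclinical": EXPERIMENTAL,
    "clinical-trial": EXPERIMENTAL,
    "non-therapeutic": EXPERIMENTAL,
}


class LabelingError(ValueError):
    pass


class ParseError(ValueError):
    pass


@dataclass
class DrugRecord:
    drug_id: str
    raw_status: str
    label: Optional[str] = None
    targets: frozenset[str] = field(default_factory=frozenset)
    ic50_nM: Optional[dict[str, float]] = None
    failure_reason: Optional[str] = None

    def with_targets(self, targets: Iterable[str]) -> "DrugRecord":
        targets = frozenset(targets)
        ic50 = None
        if self.ic50_nM is not None:
            ic50 = {t: v for t, v in self.ic50_nM.items() if t in targets}
        return replace(self, targets=targets, ic50_nM=ic50)


@dataclass
class LabeledDataset:
    drugs: list[DrugRecord]

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for d in self.drugs:
            counts[d.label] = counts.get(d.label, 0) + 1
        return counts

    def subset(self, label: str) -> list[DrugRecord]:
        return [d for d in self.drugs if d.label == label]

    def __len__(self) -> int:
        return len(self.drugs)


def assign_label(raw_status: str, status_map: Optional[dict[str, str]] = None) -> str:
    """Map a raw database status string to approved/problematic/experimental."""
    mapping = DEFAULT_STATUS_MAP if status_map is None else status_map
    key = raw_status.strip().lower()
    try:
        return mapping[key]
    except KeyError:
        raise LabelingError(
            f"unmapped drug status {raw_status!r}; known statuses: {sorted(mapping)}"
        ) from None


def load_drug_targets(
    stream: Iterable[str], status_map: Optional[dict[str, str]] = None
) -> list[DrugRecord]:
    """Parse the drug-target TSV dialect.

    Columns: drug_id, raw_status, semicolon-separated targets, and
    optionally semicolon-separated IC50 values (nM; empty field = no
    annotation) and a failure reason.  Duplicate drug ids are merged by
    target-set union; conflicting raw statuses for the same drug are an
    error.
    """
    records: dict[str, DrugRecord] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if not (3 <= len(fields) <= 5):
            raise ParseError(f"line {lineno}: expected 3-5 columns, got {len(fields)}")
        drug_id, raw_status = fields[0], fields[1]
        targets = [t for t in fields[2].split(";") if t]
        ic50: Optional[dict[str, float]] = None
        if len(fields) >= 4 and fields[3].strip():
            vals = fields[3].split(";")
            if len(vals) != len(targets):
                raise ParseError(
                    f"line {lineno}: {len(vals)} IC50 values for {len(targets)} targets"
                )
            ic50 = {}
            for t, v in zip(targets, vals):
                if v.strip():
                    ic50[t] = float(v)
        reason = fields[4].strip() if len(fields) == 5 and fields[4].strip() else None
        label = assign_label(raw_status, status_map)
        if drug_id in records:
            prev = records[drug_id]
            if prev.raw_status.strip().lower() != raw_status.strip().lower():
                raise ParseError(
                    f"line {lineno}: drug {drug_id!r} has conflicting statuses "
                    f"{prev.raw_status!r} and {raw_status!r}"
                )
            merged_ic50 = prev.ic50_nM
            if ic50:
                merged_ic50 = dict(merged_ic50 or {})
                merged_ic50.update(ic50)
            records[drug_id] = replace(
                prev,
                targets=prev.targets | frozenset(targets),
                ic50_nM=merged_ic50,
                failure_reason=prev.failure_reason or reason,
            )
        else:
            records[drug_id] = DrugRecord(
                drug_id=drug_id,
                raw_status=raw_status,
                label=label,
                targets=frozenset(targets),
                ic50_nM=ic50,
                failure_reason=reason,
            )
    return list(records.values())


def filter_affinity(
    records: Iterable[DrugRecord], ic50_max_nM: float = 30.0
) -> list[DrugRecord]:
    """Keep only targets bound tightly (IC50 strictly below the threshold).

    Targets without an IC50 annotation pass unchanged; drugs left with no
    target are dropped.
    """
    out = []
    for rec in records:
        if rec.ic50_nM:
            keep = frozenset(
                t for t in rec.targets
                if t not in rec.ic50_nM or rec.ic50_nM[t] < ic50_max_nM
            )
        else:
            keep = rec.targets
        if keep:
            out.append(rec.with_targets(keep))
    return out


def restrict_to_networks(
    records: Iterable[DrugRecord], psin: ProteinNetwork, ppi: Optional[ProteinNetwork] = None
) -> list[DrugRecord]:
    """Drop targets absent from every supplied network; drop empty drugs."""
    universe = psin.nodes
    if ppi is not None:
        universe = universe | ppi.nodes
    out = []
    for rec in records:
        keep = rec.targets & universe
        if keep:
            out.append(rec.with_targets(keep))
    return out


def dedupe_conflicting(records: Iterable[DrugRecord]) -> list[DrugRecord]:
    """Remove every drug in a target-set group with conflicting labels.

    If drugs sharing an identical target set carry both approved and
    problematic labels, the whole group goes: such groups would place the
    same instance on both sides of the decision boundary.
    """
    records = list(records)
    groups: dict[frozenset[str], set[str]] = {}
    for rec in records:
        groups.setdefault(rec.targets, set()).add(rec.label)
    bad = {
        ts for ts, labels in groups.items()
        if APPROVED in labels and PROBLEMATIC in labels
    }
    return [rec for rec in records if rec.targets not in bad]


def split_train_test(
    dataset: LabeledDataset | list[DrugRecord],
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[list[DrugRecord], list[DrugRecord], int]:
    """Class-stratified random split with target-set hygiene.

    After the stratified partition, any training drug whose target set
    exactly equals some test drug's target set is removed from training,
    so no instance effectively appears on both sides.  Returns
    ``(train, test, n_removed)``.
    """
    drugs = dataset.drugs if isinstance(dataset, LabeledDataset) else list(dataset)
    rng = random.Random(seed)
    by_label: dict[str, list[DrugRecord]] = {}
    for d in drugs:
        by_label.setdefault(d.label, []).append(d)
    train: list[DrugRecord] = []
    test: list[DrugRecord] = []
    for label in sorted(by_label):
        group = sorted(by_label[label], key=lambda d: d.drug_id)
        if len(group) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 drugs; cannot split")
        rng.shuffle(group)
        n_train = round(train_fraction * len(group))
        n_train = min(max(n_train, 1), len(group) - 1)
        train.extend(group[:n_train])
        test.extend(group[n_train:])
    test_targets = {d.targets for d in test}
    kept = [d for d in train if d.targets not in test_targets]
    return kept, test, len(train) - len(kept)


def remove_failure_group(
    dataset: LabeledDataset | list[DrugRecord], reason: str
) -> LabeledDataset:
    """Drop the problematic drugs that failed for one specific reason."""
    drugs = dataset.drugs if isinstance(dataset, LabeledDataset) else list(dataset)
    observed = {d.failure_reason for d in drugs if d.failure_reason is not None}
    if reason not in observed:
        raise ValueError(
            f"no drug carries failure reason {reason!r}; observed reasons: {sorted(observed)}"
        )
    return LabeledDataset(
        [d for d in drugs if not (d.label == PROBLEMATIC and d.failure_reason == reason)]
    )


def write_drug_targets(records: Iterable[DrugRecord], path) -> None:
    """Write records in the same TSV dialect :func:`load_drug_targets` reads."""
    with open(path, "w") as fh:
        for rec in records:
            targets = sorted(rec.targets)
            ic50 = ""
            if rec.ic50_nM:
                ic50 = ";".join(
                    f"{rec.ic50_nM[t]:g}" if t in rec.ic50_nM else "" for t in targets
                )
            reason = rec.failure_reason or ""
            line = f"{rec.drug_id}\t{rec.raw_status}\t{';'.join(targets)}"
            if ic50 or reason:
                line += f"\t{ic50}"
            if reason:
                line += f"\t{reason}"
            fh.write(line + "\n")
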