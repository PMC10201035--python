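"""AutoDock DLG log harvesting.

An AutoDock 4 docking log (``.dlg``) reports, for every completed LGA run,
a final docked state block containing one line of the form::

    DOCKED: USER    Estimated Free Energy of Binding    =   -8.41 kcal/mol

One such line per run is extracted, in order of appearance, into
:class:`~dockselect.performance.RunRecord` objects.
"""

from __future__ import annotations

import re
from typing import IO

from .performance import RunRecord

_ENERGY_RE = re.compile(r"Estimated\s+Free\s+Energy\s+of\s+Binding\s*=\s*(\S+)")


def parse_dlg(log: str | IO[str], instance_id: str, algorithm_id: str) -> list[RunRecord]:
    """Extract one binding energy per run from an AutoDock-style docking log.

    Parameters
    ----------
    log
        The log text, or an open text stream.
    instance_id, algorithm_id
        Labels attached to every extracted record (a DLG covers a single
        receptor/ligand/configuration job, so they are not in the file).

    Raises
    ------
    ValueError
        If no energy line is present ("empty log") or an energy field does
        not parse as a number (the offending line is named).
    """
    text = log if isinstance(log, str) else log.read()
    records: list[RunRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        m = _ENERGY_RE.search(line)
        if m is None:
            continue
        try:
            energy = float(m.group(1))
        except ValueError:
            raise ValueError(
                f"malformed binding-energy field {m.group(1)!r} on line {lineno}: {line.strip()!r}"
            ) from None
        records.append(
            RunRecord(
                instance_id=instance_id,
                algorithm_id=algorithm_id,
                run_index=len(records) + 1,
                binding_energy=energy,
            )
        )
    if not records:
        raise ValueError(
            "empty log: no 'Estimated Free Energy of Binding' lines found"
        )
    return records
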