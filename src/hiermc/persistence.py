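"""Versioned model-bundle persistence.

A bundle is a single joblib file holding the fitted model (any strategy),
the training-schema fingerprint and the seeds used, so a prediction run
can verify it is being applied to compatible data.
"""

from __future__ import annotations

from pathlib import Path

import joblib

FORMAT_VERSION = 1


def save_bundle(
    path: str | Path,
    model: object,
    strategy: str,
    schema_fingerprint: str,
    seeds: dict[str, int],
) -> None:
    joblib.dump(
        {
            "format_version": FORMAT_VERSION,
            "strategy": strategy,
            "model": model,
            "schema_fingerprint": schema_fingerprint,
            "seeds": dict(seeds),
        },
        path,
    )


def load_bundle(path: str | Path) -> dict:
    bundle = joblib.load(path)
    version = bundle.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"unsupported bundle format version {version!r} "
            f"(this build reads version {FORMAT_VERSION})"
        )
    return bundle
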