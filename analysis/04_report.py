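"""Render the consolidated run report from the emitted artifacts."""

from pathlib import Path

from vli.pipeline import render_report

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    print(render_report(OUT))


if __name__ == "__main__":
    main()
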