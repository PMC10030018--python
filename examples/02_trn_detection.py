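"""Detecting trial registration numbers (TRNs) in publication text.

Registry identifiers appear in abstracts and full texts in varied shapes —
plain, with a space or hyphen after the prefix, or lowercased. The detector
canonicalizes every hit so it can be compared against a trial's registered
identifier.
"""

from trialaudit import detect_trns

abstract = (
    "Methods: this randomised trial (registered as nct 01234567, "
    "cross-registered DRKS-00004871; companion study ISRCTN12345678) "
    "assessed a 12-week intervention. EudraCT 2007-004929-31 covers the EU arm. "
    "NCT0123456 is a truncated decoy that must not match."
)

for hit in detect_trns(abstract):
    print(f"offset {hit.char_offset:>3}  {hit.registry_key:<8} {hit.canonical_id}")

print()
print("Each line is one canonical identifier: the spaced/lowercased/hyphenated")
print("forms normalize to registry format, and the 7-digit decoy is rejected.")
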