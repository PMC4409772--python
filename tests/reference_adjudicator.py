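"""Independent brute-force reference for exacerbation adjudication.

Deliberately written from scratch against the rule statements — plain
loops over claim dicts, no shared code with the package — so it can serve
as the oracle for the pipeline's adjudication output.

Claims are dicts:
  medical:  {"place", "date", "adm", "disch", "dxs": [codes...]}
  pharmacy: {"class", "date"}
"""

COPD_STEMS = ("491", "492", "496")


def _is_copd(code):
    return code.replace(".", "").startswith(COPD_STEMS) if code else False


def _has_copd(dxs, primary_only):
    relevant = dxs[:1] if primary_only else dxs
    return any(_is_copd(d) for d in relevant)


def brute_force_adjudicate(medical, pharmacy, start, end, chained=False):
    """Return [(onset, type_code)] with 2=inpatient, 1=ed, 0=outpatient_rx."""
    inpt = [c for c in medical
            if c["place"] == "inpatient" and _has_copd(c["dxs"], True)
            and start <= c["adm"] <= end]
    eds = [c for c in medical
           if c["place"] == "ed" and _has_copd(c["dxs"], False)
           and start <= c["date"] <= end]
    visits = [c for c in medical
              if c["place"] in ("office", "outpatient") and _has_copd(c["dxs"], False)
              and start <= c["date"] <= end]
    fills = [f for f in pharmacy if f["class"] in ("OCS", "ANTIBIOTIC")]

    # rule (i): ED visit inside an inpatient stay counts as the stay only
    eds = [e for e in eds
           if not any(i["adm"] <= e["date"] <= i["disch"] for i in inpt)]

    severe_onsets = [i["adm"] for i in inpt] + [e["date"] for e in eds]

    # candidate pairs, rule (ii) fill absorption, rule (iii) one per visit
    rx_onsets = set()
    for v in visits:
        for f in fills:
            if 0 <= f["date"] - v["date"] <= 10:
                if all(abs(f["date"] - s) > 14 for s in severe_onsets):
                    rx_onsets.add(v["date"])

    cands = ([(i["adm"], 2) for i in inpt] + [(e["date"], 1) for e in eds]
             + [(d, 0) for d in sorted(rx_onsets)])
    cands.sort(key=lambda t: (t[0], -t[1]))

    events = []  # (anchor_onset, max_severity, last_member_onset)
    for day, sev in cands:
        if events:
            ref = events[-1][2] if chained else events[-1][0]
            if day - ref <= 14:
                anchor, top, _ = events[-1]
                events[-1] = (anchor, max(top, sev), day)
                continue
        events.append((day, sev, day))
    return [(d, s) for d, s, _ in events]
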