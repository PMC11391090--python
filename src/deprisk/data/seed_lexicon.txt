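# Illustrative depression-related seed lexicon (synthetic, non-canonical).
# A real deployment should supply a curated dictionary of symptom terms,
# drug names, and colloquial expressions; this small list only exercises
# the retrieval-sampling machinery on CJK input.
抑郁
抑郁症
失眠
绝望
难过
想哭
崩溃
自杀
无助
疲惫
焦虑
孤独
痛苦
轻生
药物
舍曲林
氟西汀
心理咨询
情绪低落
活着好累
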