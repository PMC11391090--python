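# Seed emoticon -> emotion-word map (bracketed Weibo-style emoticons).
# Editable; extend with platform-specific entries as needed.
[泪]	流泪
[悲伤]	悲伤
[伤心]	伤心
[失望]	失望
[抓狂]	抓狂
[怒]	愤怒
[哈哈]	大笑
[嘻嘻]	开心
[爱你]	喜爱
[心]	爱心
[衰]	沮丧
[可怜]	可怜
[晕]	头晕
[汗]	尴尬
[抱抱]	拥抱
[鼓掌]	鼓掌
[赞]	称赞
[思考]	思考
[睡觉]	困倦
[疑问]	疑惑
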