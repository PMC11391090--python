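"""Clean raw microblog text: emoticons, URLs, numbers, punctuation, bot
posts, duplicates, and too-short posts.

The cleaning order is fixed (emoticon substitution first, punctuation strip
last) and the raw text is kept on every post so punctuation can still be
analyzed later.
"""

from deprisk import preprocess, synthetic

config = preprocess.load_default_config()

raw = "今天[泪] 好难过 http://t.cn/abc 123。"
print("raw:    ", raw)
print("cleaned:", preprocess.clean_text(raw, config))
# The emoticon becomes its emotion word; URL, digits and punctuation vanish.

corpus = synthetic.generate_corpus(
    synthetic.preset("strong", n_users_per_class=20, seed=7))
n_before = sum(len(u.posts) for u in corpus.users)
clean, dropped = preprocess.prepare_corpus(corpus, config)
n_after = sum(len(u.posts) for u in clean.users)
print(f"posts: {n_before} raw -> {n_after} after bot/duplicate/short filtering"
      f" ({len(dropped)} users emptied)")

user = clean.users[0]
print("tokenized:", user.posts[0].tokens[:8], "...")
print("raw kept: ", user.posts[0].raw_text[:40], "...")
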