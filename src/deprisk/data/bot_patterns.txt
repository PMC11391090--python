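# Seed list of platform-generated post markers (substring match unless the
# pattern is anchored with ^ or $). Editable.
生日提醒
会员等级
会员到期
积分兑换
自动回复
抽奖平台
微博等级
红包已领取
签到成功
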