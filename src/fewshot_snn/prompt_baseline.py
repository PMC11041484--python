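"""Prefix-prompt construction for a generative zero-shot baseline.

A classification sentence is turned into a prefix prompt that ends where
the generative model's completion (its class guess) would begin:

    {text}. options are advanced cancer, advanced heart disease,
    advanced lung disease, chronic pain fibromyalgia. type of disease

If the tokenized prompt exceeds the model's context window (1024 tokens for
GPT-2), the input text is trimmed from its end, word by word, until the
prompt fits — the option list and the trailing cue are never touched.
Token counting is pluggable: the default counts whitespace tokens; an
adapter accepting a real subword tokenizer can be passed in where one is
available.  Running the generative model, and mapping its free-text output
back onto classes, are outside this module's scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .exceptions import ConfigurationError, DataError

__all__ = ["DEFAULT_LABEL_OPTIONS", "PromptTemplate", "build_prompt"]

#: The four label phrases, in the order they appear in the prompt.
DEFAULT_LABEL_OPTIONS = (
    "advanced cancer",
    "advanced heart disease",
    "advanced lung disease",
    "chronic pain fibromyalgia",
)


def whitespace_token_count(text: str) -> int:
    return len(text.split())


@dataclass(frozen=True)
class PromptTemplate:
    """Prompt scaffold: ordered label phrases, context budget, token counter."""

    label_options: tuple[str, ...] = DEFAULT_LABEL_OPTIONS
    max_context: int = 1024
    token_count: Callable[[str], int] = whitespace_token_count

    def __post_init__(self) -> None:
        if not self.label_options:
            raise ConfigurationError("label_options must be non-empty")
        object.__setattr__(self, "label_options", tuple(self.label_options))

    @property
    def scaffold(self) -> str:
        """Everything after the input text, up to where generation begins."""
        return f". options are {', '.join(self.label_options)}. type of disease"


def build_prompt(text: str, template: PromptTemplate = PromptTemplate()) -> str:
    """Assemble ``{text}{scaffold}``, trimming the text to fit the context.

    The text is shortened from its end at whitespace-word granularity until
    ``template.token_count`` of the whole prompt is within
    ``template.max_context``; the scaffold stays intact.

    Raises
    ------
    DataError
        If ``text`` is empty.
    ConfigurationError
        If the scaffold alone exceeds the context budget.
    """
    if not text.strip():
        raise DataError("input text is empty")
    scaffold = template.scaffold
    if template.token_count(scaffold) > template.max_context:
        raise ConfigurationError(
            f"prompt scaffold alone has {template.token_count(scaffold)} tokens, "
            f"exceeding max_context={template.max_context}"
        )
    if template.token_count(text + scaffold) <= template.max_context:
        return text + scaffold
    words = text.split()
    while words:
        prompt = " ".join(words) + scaffold
        if template.token_count(prompt) <= template.max_context:
            return prompt
        words.pop()
    raise DataError(
        "text cannot be trimmed to fit the context window "
        f"(max_context={template.max_context})"
    )
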